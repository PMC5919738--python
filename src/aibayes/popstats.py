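"""Population-level summaries of per-unit imbalance calls across F1 lines.

Given per-(exon, line) test flags, these routines find exons whose
frequency of imbalance change across conditions is unusually high
(enriched) or low (depleted) relative to all other exons, cross-tabulate
imbalance categories, and quantify agreement between two classifiers
with Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExonLineFlags",
    "fisher_exact_2x2",
    "exon_enrichment",
    "enrichment_table",
    "cohens_kappa",
    "classify_unit",
    "gene_ai_flag",
]

CATEGORY_NONE = "Both alpha = 1"
CATEGORY_ONE = "One alpha = 1"
CATEGORY_BOTH = "Both alpha != 1"


@dataclass
class ExonLineFlags:
    """Per-(exon, line) test outcomes.

    ``frame`` columns: ``exon``, ``line``, ``ai_env1``, ``ai_env2``,
    ``ai_diff`` (booleans). Every row is a tested data point; untested
    (exon, line) pairs are simply absent.
    """

    frame: pd.DataFrame

    REQUIRED = ("exon", "line", "ai_env1", "ai_env2", "ai_diff")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        if self.frame.duplicated(subset=["exon", "line"]).any():
            raise ValueError("duplicate (exon, line) rows")

    @property
    def n_data_points(self) -> int:
        return len(self.frame)

    def exons(self) -> list[str]:
        return list(dict.fromkeys(self.frame["exon"]))


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> float:
    """Fisher's exact p-value for the table [[a, b], [c, d]].

    One-sided alternatives test whether the odds ratio exceeds
    (``greater``) or falls below (``less``) 1; degenerate margins give
    p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative=alternative).pvalue)


def exon_enrichment(flags: ExonLineFlags, exon: str,
                    alternative: str = "greater",
                    same_lines_only: bool = False
                    ) -> tuple[int, int, float]:
    """Test one exon for excess/depletion of imbalance change across lines.

    Builds the 2x2 table of (changed, unchanged) line counts for the
    exon against the pooled data points of all other exons and returns
    ``(lines tested, lines changed, one-sided Fisher p)``. Raw p-values
    are returned (no multiplicity correction). ``same_lines_only``
    restricts the background to the lines in which the exon was tested.
    """
    df = flags.frame
    mine = df[df["exon"] == exon]
    if mine.empty:
        raise KeyError(f"exon {exon!r} not present in the flag table")
    rest = df[df["exon"] != exon]
    if same_lines_only:
        rest = rest[rest["line"].isin(mine["line"])]
    a = int(mine["ai_diff"].sum())
    b = int(len(mine) - a)
    c = int(rest["ai_diff"].sum())
    d = int(len(rest) - c)
    return len(mine), a, fisher_exact_2x2(a, b, c, d, alternative)


def enrichment_table(flags: ExonLineFlags, alternative: str = "greater",
                     with_bh: bool = False) -> pd.DataFrame:
    """Per-exon enrichment/depletion table, sorted by p-value.

    Columns: ``exon``, ``count`` (lines tested), ``ai_diff`` (lines with
    changed imbalance), ``p``. ``with_bh`` appends a Benjamini-Hochberg
    adjusted column as optional extra output.
    """
    rows = []
    for exon in flags.exons():
        n, k, p = exon_enrichment(flags, exon, alternative)
        rows.append({"exon": exon, "count": n, "ai_diff": k, "p": p})
    out = pd.DataFrame(rows).sort_values(["p", "exon"], kind="stable")
    if with_bh:
        out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    return out.reset_index(drop=True)


def cohens_kappa(confusion) -> float:
    """Cohen's kappa from a 2x2 (or larger square) confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and
    chance agreement p_e from the margins. Degenerate margins with
    p_e = 1 leave kappa undefined and raise.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion entries must be non-negative")
    n = m.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(m) / n
    p_e = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    if p_e >= 1.0:
        raise ValueError("degenerate margins: chance agreement is 1, "
                         "kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def classify_unit(ai_env1: bool, ai_env2: bool) -> str:
    """Imbalance category of one data point from the per-condition calls."""
    n = int(bool(ai_env1)) + int(bool(ai_env2))
    return (CATEGORY_NONE, CATEGORY_ONE, CATEGORY_BOTH)[n]


def gene_ai_flag(exon_line_flags) -> bool:
    """Gene-level roll-up: flagged when any exon in any line shows imbalance."""
    return bool(np.asarray(exon_line_flags, dtype=bool).any())
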