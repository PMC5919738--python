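"""Reading and writing count tables, bias tables and result files.

File dialects (all UTF-8 TSV with a mandatory header):

* count table — ``unit_id  condition  replicate  x_maternal  y_paternal
  z_unassigned``; exactly two distinct condition labels per file.
* bias table — ``unit_id  condition  r_m  r_p``; a row with unit_id ``*``
  (and optionally condition ``*``) sets the default for units/conditions
  not listed explicitly.
* results — one row per unit with posterior summaries and test flags, see
  :func:`write_results`.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    SUMMARY_PARAMS,
    AlleleCountSet,
    BiasSpec,
    ParamSummary,
    PosteriorSummary,
    QCConfig,
)

__all__ = [
    "CountsParseError",
    "read_counts_table",
    "write_counts_table",
    "read_bias_table",
    "bias_for_unit",
    "apply_qc",
    "count_data_points",
    "write_results",
    "read_results",
]

COUNT_COLUMNS = (
    "unit_id",
    "condition",
    "replicate",
    "x_maternal",
    "y_paternal",
    "z_unassigned",
)


class CountsParseError(ValueError):
    """Raised for malformed count/bias tables; names the offending row."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CountsParseError(f"{path}: missing column(s) {', '.join(missing)}")


def read_counts_table(path) -> list[AlleleCountSet]:
    """Read a TSV count table into one :class:`AlleleCountSet` per unit.

    Row order within the file determines replicate order. Malformed rows
    are reported with their line number (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, COUNT_COLUMNS, path)

    # data rows start at file line 2
    lines = df.index.to_numpy() + 2
    for col in ("replicate", "x_maternal", "y_paternal", "z_unassigned"):
        nums = pd.to_numeric(df[col], errors="coerce")
        bad = nums.isna() | (nums != nums.round()) | (nums < 0)
        if col == "replicate":
            bad |= nums < 1
        if bad.any():
            row = int(lines[bad.to_numpy()][0])
            raise CountsParseError(
                f"{path}, line {row}: column {col!r} must be a "
                f"non-negative integer (got {df[col][bad].iloc[0]!r})"
            )
        df[col] = nums.astype(np.int64)

    conditions = list(dict.fromkeys(df["condition"]))  # first-appearance order
    if len(conditions) != 2:
        raise CountsParseError(
            f"{path}: expected exactly 2 condition labels, found "
            f"{len(conditions)}: {conditions}"
        )

    dup = df.duplicated(subset=["unit_id", "condition", "replicate"], keep=False)
    if dup.any():
        row = int(lines[dup.to_numpy()][0])
        key = df.loc[dup].iloc[0]
        raise CountsParseError(
            f"{path}, line {row}: duplicate (unit, condition, replicate) key "
            f"({key['unit_id']!r}, {key['condition']!r}, {key['replicate']})"
        )

    out: list[AlleleCountSet] = []
    for unit_id, grp in df.groupby("unit_id", sort=False):
        parts = {c: g for c, g in grp.groupby("condition", sort=False)}
        missing = [c for c in conditions if c not in parts]
        if missing:
            raise CountsParseError(
                f"{path}: unit {unit_id!r} lacks rows for condition(s) "
                f"{missing}"
            )
        out.append(
            AlleleCountSet(
                unit_id=str(unit_id),
                conditions=(conditions[0], conditions[1]),
                x=tuple(parts[c]["x_maternal"].to_numpy() for c in conditions),
                y=tuple(parts[c]["y_paternal"].to_numpy() for c in conditions),
                z=tuple(parts[c]["z_unassigned"].to_numpy() for c in conditions),
            )
        )
    return out


def write_counts_table(path, data: Iterable[AlleleCountSet]) -> None:
    """Write units back to the TSV count-table dialect (inverse of reading)."""
    rows = []
    for unit in data:
        for i in range(2):
            for k in range(unit.n_reps[i]):
                rows.append({
                    "unit_id": unit.unit_id,
                    "condition": unit.conditions[i],
                    "replicate": k + 1,
                    "x_maternal": int(unit.x[i][k]),
                    "y_paternal": int(unit.y[i][k]),
                    "z_unassigned": int(unit.z[i][k]),
                })
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


def read_bias_table(path, conditions: Sequence[str],
                    allow_above_one: bool = False) -> dict[str, BiasSpec]:
    """Read a TSV bias table into per-unit :class:`BiasSpec` objects.

    ``conditions`` gives the two condition labels (in model order) the
    rates apply to. Rows with unit_id ``*`` define the fallback returned
    by :func:`bias_for_unit` for units without explicit rows; within a
    unit, a row with condition ``*`` applies to both conditions.
    """
    if len(conditions) != 2:
        raise ValueError("exactly two condition labels are required")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ("unit_id", "condition", "r_m", "r_p"), path)
    for col in ("r_m", "r_p"):
        df[col] = pd.to_numeric(df[col], errors="raise")

    out: dict[str, BiasSpec] = {}
    for unit_id, grp in df.groupby("unit_id", sort=False):
        rm: list[float | None] = [None, None]
        rp: list[float | None] = [None, None]
        for _, row in grp.iterrows():
            targets = (0, 1) if row["condition"] == "*" else (
                conditions.index(row["condition"]),)
            for i in targets:
                rm[i] = float(row["r_m"])
                rp[i] = float(row["r_p"])
        if None in rm or None in rp:
            raise CountsParseError(
                f"{path}: unit {unit_id!r} has bias rates for only one "
                "condition"
            )
        out[str(unit_id)] = BiasSpec(
            r_m=(rm[0], rm[1]), r_p=(rp[0], rp[1]),
            allow_above_one=allow_above_one,
        )
    return out


def bias_for_unit(table: Mapping[str, BiasSpec], unit_id: str) -> BiasSpec:
    """Look up the bias rates for a unit, falling back to the ``*`` default."""
    if unit_id in table:
        return table[unit_id]
    if "*" in table:
        return table["*"]
    raise KeyError(
        f"no bias rates for unit {unit_id!r} and no '*' default row"
    )


def apply_qc(
    data: Iterable[AlleleCountSet], cfg: QCConfig = QCConfig()
) -> tuple[list[AlleleCountSet], list[tuple[AlleleCountSet, str]]]:
    """Partition units into (kept, dropped-with-reason) under the QC rules.

    The reason reported for a dropped unit is the first failing rule in
    the order: assigned fraction, per-condition assigned reads, total
    reads. Idempotent: re-applying to the kept list drops nothing.
    """
    kept: list[AlleleCountSet] = []
    dropped: list[tuple[AlleleCountSet, str]] = []
    for unit in data:
        reason = _qc_failure(unit, cfg)
        if reason is None:
            kept.append(unit)
        else:
            dropped.append((unit, reason))
    return kept, dropped


def _qc_failure(unit: AlleleCountSet, cfg: QCConfig) -> str | None:
    pct = 100.0 * cfg.min_assigned_fraction
    if cfg.fraction_per_condition:
        for i in range(2):
            if unit.assigned_fraction(i) < cfg.min_assigned_fraction:
                return (f"assigned fraction < {pct:g}% in condition "
                        f"{unit.conditions[i]!r}")
    elif unit.assigned_fraction() < cfg.min_assigned_fraction:
        return f"assigned fraction < {pct:g}%"
    for i in range(2):
        if unit.assigned_sum(i) < cfg.min_assigned_reads:
            return (f"min_assigned_reads in condition {i + 1} "
                    f"({unit.conditions[i]!r}): {unit.assigned_sum(i)} < "
                    f"{cfg.min_assigned_reads}")
    if unit.total_reads() < cfg.min_total_reads:
        return f"total reads {unit.total_reads()} < {cfg.min_total_reads}"
    return None


def count_data_points(informative) -> int:
    """Number of informative (exon, line) cells in a binary indicator matrix.

    A "data point" is one exon measured in one F1 line; the count is the
    double sum over the exon-by-line indicator matrix.
    """
    m = np.asarray(informative)
    if m.size and not np.isin(m, (0, 1)).all():
        raise ValueError("informative matrix entries must be 0 or 1")
    return int(m.sum())


_RESULT_FIELDS = ["mean", "median", "ci_low", "ci_high", "ess"]


def write_results(path, summaries: Sequence[PosteriorSummary]) -> None:
    """Write posterior summaries as TSV, one row per unit.

    Columns: ``unit_id``, ``level``, then ``<param>_<field>`` for each
    parameter (alpha1, alpha2, alpha_ratio, theta1, theta2) and field
    (mean, median, ci_low, ci_high, ess), then the three ``reject_h0*``
    flags and ``low_ess_warning``. Values round-trip through
    :func:`read_results`.
    """
    rows = []
    for s in summaries:
        row: dict[str, object] = {"unit_id": s.unit_id, "level": s.level}
        for pname in SUMMARY_PARAMS:
            p: ParamSummary = getattr(s, pname)
            if p.ci_low > p.ci_high:
                raise ValueError(
                    f"unit {s.unit_id!r}: {pname} CI lower bound exceeds upper"
                )
            for f in _RESULT_FIELDS:
                row[f"{pname}_{f}"] = repr(float(getattr(p, f)))
        for flag in ("reject_h01", "reject_h02", "reject_h03",
                     "low_ess_warning"):
            row[flag] = int(getattr(s, flag))
        rows.append(row)
    cols = ["unit_id", "level"]
    cols += [f"{p}_{f}" for p in SUMMARY_PARAMS for f in _RESULT_FIELDS]
    cols += ["reject_h01", "reject_h02", "reject_h03", "low_ess_warning"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_results(path) -> list[PosteriorSummary]:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        params = {
            pname: ParamSummary(
                **{f: float(row[f"{pname}_{f}"]) for f in _RESULT_FIELDS})
            for pname in SUMMARY_PARAMS
        }
        out.append(
            PosteriorSummary(
                unit_id=str(row["unit_id"]),
                level=float(row["level"]),
                **params,
                reject_h01=bool(row["reject_h01"]),
                reject_h02=bool(row["reject_h02"]),
                reject_h03=bool(row["reject_h03"]),
                low_ess_warning=bool(row["low_ess_warning"]),
            )
        )
    return out


def results_to_frame(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    """Posterior summaries as a numeric DataFrame (one row per unit)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"unit_id": s.unit_id, "level": s.level}
        for pname in SUMMARY_PARAMS:
            p = getattr(s, pname)
            for f in _RESULT_FIELDS:
                row[f"{pname}_{f}"] = float(getattr(p, f))
        for flag in ("reject_h01", "reject_h02", "reject_h03",
                     "low_ess_warning"):
            row[flag] = bool(getattr(s, flag))
        rows.append(row)
    return pd.DataFrame(rows)
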