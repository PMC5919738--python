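"""Assignment-bias rates from a pair of haplotype sequences.

The recipe: enumerate every possible read of length L from each
haplotype, "align" it to both haplotypes, and record the fraction of
reads that align strictly better to their haplotype of origin — that
fraction is the assignment rate (r_m from the maternal haplotype, r_p
from the paternal). Because the haplotypes here are equal-length
SNP-substituted references, alignment reduces to a positional Hamming
comparison over the read's window of origin; a read assigns to the
haplotype with strictly fewer mismatches and ties are unassigned.
Positions containing N in the read or either reference are ignored.

Real-aligner effects (indels, paralogs, sequencing error) are out of
scope; externally measured rates can be supplied through the bias table
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

__all__ = [
    "HaplotypePair",
    "classify_read",
    "estimate_rates",
    "rates_from_fasta",
]

_ALPHABET = set("ACGTN")

MATERNAL = "maternal"
PATERNAL = "paternal"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HaplotypePair:
    """Two same-length haplotype sequences and a read length."""

    maternal_seq: str
    paternal_seq: str
    read_length: int

    def __post_init__(self) -> None:
        m = self.maternal_seq.upper()
        p = self.paternal_seq.upper()
        object.__setattr__(self, "maternal_seq", m)
        object.__setattr__(self, "paternal_seq", p)
        if len(m) != len(p):
            raise ValueError("haplotype sequences must have equal length")
        if not (set(m) | set(p)) <= _ALPHABET:
            raise ValueError("sequences must be over A, C, G, T, N")
        if not 1 <= self.read_length <= len(m):
            raise ValueError("require 1 <= read_length <= sequence length")

    def __len__(self) -> int:
        return len(self.maternal_seq)

    def n_starts(self) -> int:
        return len(self) - self.read_length + 1


def _mismatches(read: str, ref: str) -> int:
    """Positional mismatches, ignoring positions with N on either side."""
    return sum(1 for a, b in zip(read, ref)
               if a != b and a != "N" and b != "N")


def classify_read(read: str, start: int, pair: HaplotypePair) -> str:
    """Assign a read to the haplotype it matches strictly better.

    ``start`` is the 0-based origin of the read; the read is compared
    against both haplotypes over [start, start + len(read)). Equal
    mismatch counts leave the read unassigned.
    """
    end = start + len(read)
    if start < 0 or end > len(pair):
        raise ValueError(f"read window [{start}, {end}) out of bounds")
    read = read.upper()
    mm = _mismatches(read, pair.maternal_seq[start:end])
    mp = _mismatches(read, pair.paternal_seq[start:end])
    if mm < mp:
        return MATERNAL
    if mp < mm:
        return PATERNAL
    return UNASSIGNED


def estimate_rates(pair: HaplotypePair) -> tuple[float, float]:
    """(r_m, r_p): assignable fractions of all possible reads per haplotype.

    All N - L + 1 start positions are enumerated from each haplotype;
    r_m is the fraction of maternal-origin reads classified maternal,
    r_p likewise for paternal. Both lie in [0, 1]; identical haplotypes
    give (0, 0), haplotypes differing everywhere give (1, 1).
    """
    n_starts = pair.n_starts()
    L = pair.read_length
    hits_m = hits_p = 0
    for s in range(n_starts):
        if classify_read(pair.maternal_seq[s:s + L], s, pair) == MATERNAL:
            hits_m += 1
        if classify_read(pair.paternal_seq[s:s + L], s, pair) == PATERNAL:
            hits_p += 1
    return hits_m / n_starts, hits_p / n_starts


def rates_from_fasta(path, read_length: int) -> dict[str, tuple[float, float]]:
    """Estimate (r_m, r_p) for every unit in a FASTA of haplotype pairs.

    Records are paired by unit via the suffixes ``_m`` and ``_p`` on the
    record ids (e.g. ``exon1_m`` / ``exon1_p``).
    """
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    units: dict[str, dict[str, str]] = {}
    for rid, seq in records.items():
        if rid.endswith("_m"):
            units.setdefault(rid[:-2], {})["m"] = seq
        elif rid.endswith("_p"):
            units.setdefault(rid[:-2], {})["p"] = seq
        else:
            raise ValueError(f"record id {rid!r} lacks an _m/_p suffix")
    out = {}
    for unit, seqs in sorted(units.items()):
        if set(seqs) != {"m", "p"}:
            raise ValueError(f"unit {unit!r} is missing one haplotype")
        pair = HaplotypePair(seqs["m"], seqs["p"], read_length)
        out[unit] = estimate_rates(pair)
    return out
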