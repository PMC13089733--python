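"""Base composition and strand-asymmetry (skew) statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed on
counts or percentages interchangeably (the statistic is scale invariant).
Mitochondrial strands are compositionally asymmetric; the skews quantify
that asymmetry per feature and genome-wide.

Per-feature profiles are computed on the *plus-strand* slice of each
feature's span regardless of the feature's own strand — the convention
under which the single minus-strand protein-coding gene of a holothurian
mitogenome (nad6) shows sign-inverted skews relative to its plus-strand
peers.  Coding-strand profiles are available via ``coding_strand=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError
from .genome_io import MitogenomeRecord

#: column order of the emitted per-feature table
TABLE_COLUMNS = ["T_pct", "C_pct", "A_pct", "G_pct",
                 "AT_pct", "AT_skew", "GC_skew"]


def skew(x: float, y: float) -> float:
    """(x - y) / (x + y); NaN when x + y == 0 (undefined, never 0)."""
    total = x + y
    if total == 0:
        return math.nan
    return (x - y) / total


@dataclass
class CompositionProfile:
    """Counts, percentages and skews for one DNA stretch.

    ``N`` bases are excluded from counts and denominators and tallied in
    ``n_ambiguous``.  Undefined skews (zero denominator) are NaN.
    """

    counts: dict[str, int]
    n_ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pct(self, base: str) -> float:
        return 100.0 * self.counts[base] / self.total

    @property
    def at_pct(self) -> float:
        return self.pct("A") + self.pct("T")

    @property
    def at_skew(self) -> float:
        return skew(self.counts["A"], self.counts["T"])

    @property
    def gc_skew(self) -> float:
        return skew(self.counts["G"], self.counts["C"])

    def as_row(self) -> dict[str, float]:
        return {
            "T_pct": self.pct("T"), "C_pct": self.pct("C"),
            "A_pct": self.pct("A"), "G_pct": self.pct("G"),
            "AT_pct": self.at_pct,
            "AT_skew": self.at_skew, "GC_skew": self.gc_skew,
        }


def base_composition(seq: str) -> CompositionProfile:
    """Tally A/C/G/T (N excluded) and derive percentages and skews."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n_amb = seq.count("N")
    if sum(counts.values()) == 0:
        raise ValidationError("empty or all-ambiguous sequence")
    if n_amb > 0.10 * len(seq):
        warnings.warn(f"sequence is {100*n_amb/len(seq):.0f}% N", stacklevel=2)
    return CompositionProfile(counts=counts, n_ambiguous=n_amb)


def per_feature_composition(record: MitogenomeRecord,
                            coding_strand: bool = False) -> pd.DataFrame:
    """One composition row per feature plus a genome-wide ``mitogenome`` row.

    Requires a sequence-bearing record.  With ``coding_strand=True``,
    minus-strand features are reverse-complemented before tallying.
    """
    if record.sequence is None:
        raise ValidationError(
            "per-feature composition needs a sequence; read the record from "
            "GenBank or attach a FASTA sequence"
        )
    rows, index = [], []
    for f in record.features:
        chunk = record.feature_slice(f)
        if coding_strand and f.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        rows.append(base_composition(chunk).as_row())
        index.append(f.name)
    rows.append(base_composition(record.sequence).as_row())
    index.append("mitogenome")
    return pd.DataFrame(rows, index=pd.Index(index, name="Gene"),
                        columns=TABLE_COLUMNS)


def format_composition_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round to print precision: percentages 1 dp, skews 3 dp."""
    out = table.copy()
    for col in ("T_pct", "C_pct", "A_pct", "G_pct", "AT_pct"):
        out[col] = out[col].round(1)
    for col in ("AT_skew", "GC_skew"):
        out[col] = out[col].round(3)
    return out
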