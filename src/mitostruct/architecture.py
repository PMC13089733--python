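"""Feature geometry of an annotated circular genome.

Computes per-feature lengths, the signed gap between each pair of adjacent
features (positive = intergenic spacer, negative = overlap, zero =
abutting), a four-way typology of overlaps, strand tallies, and the linear
gene order used downstream for rearrangement comparison.

The gap between consecutive features is ``start(next) - end(prev) - 1``,
the convention under which published annotation tables print their
"space/overlap" column.  The origin-spanning stretch between the last and
first feature of a circular record is *not* a gap entry; it is reported
separately as the unannotated wraparound (the putative control region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ValidationError
from .gene_order import GeneOrderSignature
from .genome_io import GeneFeature, MitogenomeRecord

#: overlap typology, in priority order
OVERLAP_TYPES = ("opposite_strand", "stop_codon", "pcg_pcg", "other")


def feature_length(feature: GeneFeature, genome_length: int | None = None,
                   circular: bool = True) -> int:
    """Length in bp of a feature, supporting origin-wrapping features.

    A wrapping feature (end < start) on a circular genome of length L spans
    ``(L - start + 1) + end`` bases.
    """
    if feature.end >= feature.start:
        return feature.end - feature.start + 1
    if not circular:
        raise ValidationError(
            f"{feature.name}: end < start on a linear record"
        )
    if genome_length is None:
        raise ValidationError(
            f"{feature.name}: genome length required for a wrapping feature"
        )
    return (genome_length - feature.start + 1) + feature.end


@dataclass
class GapRecord:
    """Signed gap between two adjacent features.

    ``overlap_type`` is set iff ``gap < 0``.
    """

    upstream: GeneFeature
    downstream: GeneFeature
    gap: int
    overlap_type: str | None = None

    @property
    def pair(self) -> str:
        return f"{self.upstream.name}->{self.downstream.name}"


@dataclass
class ArchitectureSummary:
    n_spacers: int
    n_overlaps: int
    max_spacer: tuple[str, int] | None
    max_overlap: tuple[str, int] | None
    wraparound_unannotated: int
    strand_counts: dict[str, dict[str, int]]
    overlap_type_counts: dict[str, int] = field(default_factory=dict)


def classify_overlap(gap: GapRecord) -> str:
    """Assign one of the four overlap types, in priority order.

    1. ``opposite_strand`` — the two features lie on different strands;
    2. ``stop_codon`` — the overlapped bases fall entirely within the
       upstream protein-coding gene's (possibly incomplete) stop codon,
       i.e. the overlap length does not exceed the stop codon's length;
    3. ``pcg_pcg`` — both features are protein-coding genes;
    4. ``other`` — none of the above.

    The containment reading of rule 2 is what separates a termination-codon
    overlap (a downstream gene starting inside the 1–3 bp stop) from a
    deeper overlap that merely *includes* the stop, such as the 7 bp
    atp8/atp6 case, which rule 3 claims.
    """
    if gap.gap >= 0:
        raise ValidationError("classify_overlap requires gap < 0")
    up, down = gap.upstream, gap.downstream
    if up.strand != down.strand:
        return "opposite_strand"
    if up.kind == "PCG" and up.stop_codon:
        if -gap.gap <= len(up.stop_codon):
            return "stop_codon"
    if up.kind == "PCG" and down.kind == "PCG":
        return "pcg_pcg"
    return "other"


def compute_gaps(record: MitogenomeRecord) -> list[GapRecord]:
    """Signed gaps for every consecutive feature pair, sorted by start.

    Pairs where the downstream feature is entirely contained in the
    upstream one are skipped with a warning: a containment depth is not a
    meaningful gap.  Fewer than two features yields an empty list.
    """
    feats = record.features
    gaps: list[GapRecord] = []
    for prev, nxt in zip(feats, feats[1:]):
        if nxt.end <= prev.end and nxt.start >= prev.start:
            warnings.warn(
                f"{nxt.name} ({nxt.start}-{nxt.end}) is nested inside "
                f"{prev.name} ({prev.start}-{prev.end}); pair skipped",
                stacklevel=2,
            )
            continue
        g = GapRecord(upstream=prev, downstream=nxt,
                      gap=nxt.start - prev.end - 1)
        if g.gap < 0:
            g.overlap_type = classify_overlap(g)
        gaps.append(g)
    return gaps


def wraparound_size(record: MitogenomeRecord) -> int:
    """Unannotated bp between the last feature's end and the first's start,
    across the origin of a circular record (0 for linear or empty)."""
    if not record.features or not record.circular:
        return 0
    first, last = record.features[0], record.features[-1]
    return (record.length - max(f.end for f in record.features)) \
        + (first.start - 1)


def summarize_architecture(record: MitogenomeRecord) -> ArchitectureSummary:
    """Spacer/overlap counts, extrema with pair labels, strand tallies."""
    gaps = compute_gaps(record)
    spacers = [g for g in gaps if g.gap > 0]
    overlaps = [g for g in gaps if g.gap < 0]
    strand_counts: dict[str, dict[str, int]] = {}
    for f in record.features:
        strand_counts.setdefault(f.kind, {"+": 0, "-": 0})[f.strand] += 1
    type_counts = {t: 0 for t in OVERLAP_TYPES}
    for g in overlaps:
        type_counts[g.overlap_type] += 1
    max_spacer = max(spacers, key=lambda g: g.gap, default=None)
    max_overlap = min(overlaps, key=lambda g: g.gap, default=None)
    return ArchitectureSummary(
        n_spacers=len(spacers),
        n_overlaps=len(overlaps),
        max_spacer=(max_spacer.pair, max_spacer.gap) if max_spacer else None,
        max_overlap=(max_overlap.pair, max_overlap.gap) if max_overlap else None,
        wraparound_unannotated=wraparound_size(record),
        strand_counts=strand_counts,
        overlap_type_counts=type_counts,
    )


def extract_gene_order(record: MitogenomeRecord) -> GeneOrderSignature:
    """The record's gene order as a signed (name, strand) sequence."""
    return GeneOrderSignature(
        label=record.id,
        order=[(f.name, f.strand) for f in record.features],
        circular=record.circular,
    )


def length_conservation_residual(record: MitogenomeRecord) -> int:
    """Residual of the coverage identity

    ``sum(lengths) + sum(spacers) - sum(|overlaps|) + wraparound - L``

    which is 0 for any record without nested features (telescoping of
    adjacent spans).  Nested pairs are excluded by :func:`compute_gaps`, in
    which case the identity need not hold and the residual is informative.
    """
    gaps = compute_gaps(record)
    total = sum(feature_length(f, record.length, record.circular)
                for f in record.features)
    total += sum(g.gap for g in gaps)
    total += wraparound_size(record)
    return total - record.length
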