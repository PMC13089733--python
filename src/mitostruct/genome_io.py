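"""Domain types and file I/O for annotated mitochondrial genomes.

The pipeline's inputs are (a) GenBank flat files, (b) a plain tab-separated
gene-feature table (one row per gene, 1-based inclusive coordinates — the
layout in which mitogenome papers print their annotation tables), and
(c) FASTA alignments for the population-genetic statistics.

Coordinates are 1-based inclusive everywhere in the public API; the zero
based half-open convention used by Biopython exists only at the GenBank
boundary and never appears in files.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, ValidationError

FEATURE_KINDS = ("PCG", "tRNA", "rRNA", "other")

#: name-prefix → feature kind, the convention used by mitogenome annotation
#: tables (cox/nad/atp/cob are the 13 canonical protein-coding genes).
_KIND_PREFIXES = (
    ("cox", "PCG"),
    ("nad", "PCG"),
    ("atp", "PCG"),
    ("cob", "PCG"),
    ("trn", "tRNA"),
    ("rrn", "rRNA"),
)

_GENE_TABLE_COLUMNS = (
    "Gene", "Start", "End", "Strand", "Length",
    "StartCodon", "StopCodon", "Anticodon",
)


def infer_kind(name: str) -> str:
    """Classify a gene label as PCG / tRNA / rRNA / other by its prefix."""
    low = name.lower()
    for prefix, kind in _KIND_PREFIXES:
        if low.startswith(prefix):
            return kind
    return "other"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with 1-based inclusive coordinates.

    Names need not be unique in a record (mitogenomes carry duplicated
    trnL/trnS paralogs); feature identity is the ``(name, start)`` pair.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.start < 1 or self.end < 1:
            raise ValidationError(
                f"{self.name}: coordinates must be >= 1 "
                f"(got {self.start}-{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.name}: strand must be '+' or '-'")
        if self.kind == "tRNA" and self.anticodon is not None \
                and len(self.anticodon) != 3:
            raise ValidationError(
                f"{self.name}: anticodon {self.anticodon!r} is not 3 nt"
            )

    @property
    def identity(self) -> tuple[str, int]:
        return (self.name, self.start)

    @property
    def wraps(self) -> bool:
        """True when the feature spans the origin (end < start)."""
        return self.end < self.start


@dataclass
class MitogenomeRecord:
    """A (usually circular) annotated mitochondrial genome."""

    id: str
    length: int
    circular: bool = True
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("genome length must be positive")
        if self.sequence is not None:
            self.sequence = normalize_sequence(self.sequence)
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"sequence length {len(self.sequence)} != declared "
                    f"length {self.length}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if max(f.start, f.end) > self.length:
                raise ValidationError(
                    f"{f.name}: coordinates exceed genome length {self.length}"
                )
            if f.wraps and not self.circular:
                raise ValidationError(
                    f"{f.name}: wraps the origin on a linear record"
                )

    def feature_slice(self, feature: GeneFeature) -> str:
        """Plus-strand genome slice of a feature's span (wrap-aware)."""
        if self.sequence is None:
            raise ValidationError(
                f"record {self.id} carries no sequence; supply a GenBank or "
                "FASTA-backed record for sequence-level analyses"
            )
        if feature.wraps:
            return (self.sequence[feature.start - 1:]
                    + self.sequence[:feature.end])
        return self.sequence[feature.start - 1:feature.end]


@dataclass
class AlignmentMatrix:
    """A rectangular multiple-sequence alignment (rows = sequences)."""

    ids: list[str]
    sites: np.ndarray  # (n, L) array of dtype '<U1'

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype="<U1")
        if self.sites.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.ids) != self.sites.shape[0]:
            raise AlignmentError("one id required per alignment row")
        if self.sites.shape[0] < 1:
            raise AlignmentError("alignment needs at least one sequence")

    @property
    def n(self) -> int:
        return self.sites.shape[0]

    @property
    def length(self) -> int:
        return self.sites.shape[1]

    def row(self, i: int) -> str:
        return "".join(self.sites[i])


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA 'U' to 'T'; reject characters outside ACGTN-."""
    up = seq.upper()
    if "U" in up:
        warnings.warn("RNA-style 'U' bases normalized to 'T'", stacklevel=3)
        up = up.replace("U", "T")
    bad = set(up) - set("ACGTN-")
    if bad:
        raise FormatError(f"unexpected sequence characters: {sorted(bad)}")
    return up


# ---------------------------------------------------------------------------
# gene-feature TSV
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> MitogenomeRecord:
    """Read a tab-separated gene-feature table.

    Mandatory columns: ``Gene``, ``Start``, ``End``, ``Strand``; optional:
    ``Length``, ``StartCodon``, ``StopCodon``, ``Anticodon``.  Header pragmas
    ``#id=``, ``#length=`` and ``#circular=`` may precede the header row;
    without a length pragma the genome length defaults to ``max(end)``.
    A ``Length`` column, when present, is validated against
    ``end - start + 1`` and any mismatch raised as a warning (printed tables
    occasionally carry typos), never an error.
    """
    path = Path(path)
    pragmas: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            pragmas[key.strip().lower()] = value.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path}: no header row found")

    reader = csv.reader(io.StringIO("\n".join(body)), delimiter="\t")
    header = next(reader)
    missing = {"Gene", "Start", "End", "Strand"} - set(header)
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {sorted(missing)}")
    col = {name: header.index(name) for name in header}

    def cell(row: list[str], name: str) -> str | None:
        idx = col.get(name)
        if idx is None or idx >= len(row):
            return None
        value = row[idx].strip()
        return value or None

    circular = pragmas.get("circular", "true").lower() != "false"
    features = []
    for row in reader:
        if not any(value.strip() for value in row):
            continue
        name = cell(row, "Gene")
        try:
            start = int(cell(row, "Start"))
            end = int(cell(row, "End"))
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: non-integer coordinate in row for {name!r}"
            ) from exc
        strand = cell(row, "Strand")
        if strand in ("−", "–"):  # minus/en-dash from typeset tables
            strand = "-"
        if end < start and not circular:
            raise ValidationError(
                f"{path}: {name} has start > end on a linear record"
            )
        feature = GeneFeature(
            name=name,
            kind=infer_kind(name),
            start=start,
            end=end,
            strand=strand,
            anticodon=cell(row, "Anticodon"),
            start_codon=cell(row, "StartCodon"),
            stop_codon=cell(row, "StopCodon"),
        )
        printed = cell(row, "Length")
        if printed is not None:
            span = end - start + 1 if end >= start else None
            if span is not None and int(printed) != span:
                warnings.warn(
                    f"{name}: printed length {printed} != computed {span}",
                    stacklevel=2,
                )
        features.append(feature)

    length = int(pragmas["length"]) if "length" in pragmas else (
        max((f.end for f in features), default=0)
        or max((f.start for f in features), default=1)
    )
    return MitogenomeRecord(
        id=pragmas.get("id", path.stem),
        length=length,
        circular=circular,
        features=features,
    )


def write_gene_table(record: MitogenomeRecord, path: str | Path) -> None:
    """Write the canonical gene-table TSV (inverse of :func:`read_gene_table`)."""
    lines = [f"#id={record.id}",
             f"#length={record.length}",
             f"#circular={'true' if record.circular else 'false'}",
             "\t".join(_GENE_TABLE_COLUMNS)]
    for f in record.features:
        span = f.end - f.start + 1 if f.end >= f.start else ""
        lines.append("\t".join(str(x) for x in (
            f.name, f.start, f.end, f.strand, span,
            f.start_codon or "", f.stop_codon or "", f.anticodon or "",
        )))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_reference_record() -> MitogenomeRecord:
    """The packaged *Holothuria atra* annotation table (GenBank PV998923).

    37 features — 13 protein-coding genes, 22 tRNAs and 2 rRNAs — on a
    15,788 bp circular genome; coordinate-only (no sequence).
    """
    return read_gene_table(Path(__file__).parent / "data" / "h_atra_gene_table.tsv")


def load_reference_composition():
    """The published per-gene composition table as a pandas DataFrame.

    Columns: Gene, T_pct, C_pct, A_pct, G_pct, AT_pct, AT_skew, GC_skew
    (percentages to 1 decimal, skews to 3, as printed).
    """
    import pandas as pd

    return pd.read_csv(
        Path(__file__).parent / "data" / "h_atra_composition.tsv", sep="\t"
    )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GENBANK_FEATURE_TYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                          "misc_feature": "other"}


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read a GenBank flat file into a :class:`MitogenomeRecord`.

    CDS/tRNA/rRNA features are used (plain ``gene`` features are redundant
    mirrors and skipped); ``complement(...)`` maps to the '-' strand and an
    origin-spanning ``join(...)`` is accepted only on circular records.
    """
    path = Path(path)
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a parseable GenBank file ({exc})") from exc

    circular = seqrec.annotations.get("topology", "linear") == "circular"
    length = len(seqrec.seq)
    features: list[GeneFeature] = []
    for sf in seqrec.features:
        kind = _GENBANK_FEATURE_TYPES.get(sf.type)
        if kind is None:
            continue
        name = (sf.qualifiers.get("gene") or sf.qualifiers.get("product")
                or sf.qualifiers.get("locus_tag") or ["?"])[0]
        loc = sf.location
        if isinstance(loc, CompoundLocation):
            if not circular:
                raise FormatError(
                    f"{path}: {name} joins across the origin of a linear record"
                )
            parts = loc.parts
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
        else:
            start = int(loc.start) + 1
            end = int(loc.end)
        strand = "-" if loc.strand == -1 else "+"
        features.append(GeneFeature(
            name=name, kind=kind, start=start, end=end, strand=strand,
            anticodon=(sf.qualifiers.get("anticodon") or [None])[0],
            start_codon=(sf.qualifiers.get("start_codon") or [None])[0],
            stop_codon=(sf.qualifiers.get("stop_codon") or [None])[0],
        ))
    if not features:
        raise FormatError(f"{path}: no CDS/tRNA/rRNA features found")
    return MitogenomeRecord(
        id=seqrec.id, length=length, circular=circular,
        sequence=str(seqrec.seq), features=features,
    )


def write_genbank(record: MitogenomeRecord, path: str | Path,
                  transl_table: int = 9) -> None:
    """Write a record (sequence required) as a GenBank flat file."""
    if record.sequence is None:
        raise ValidationError("GenBank output requires a sequence")
    seqrec = SeqRecord(
        Seq(record.sequence), id=record.id, name=record.id[:16],
        description="synthetic annotated mitogenome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, record.length, strand),
                SimpleLocation(0, f.end, strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers: dict[str, list] = {"gene": [f.name]}
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}.get(f.kind, "misc_feature")
        if f.kind == "PCG":
            qualifiers["transl_table"] = [str(transl_table)]
        for key, value in (("anticodon", f.anticodon),
                           ("start_codon", f.start_codon),
                           ("stop_codon", f.stop_codon)):
            if value is not None:
                qualifiers[key] = [value]
        seqrec.features.append(SeqFeature(loc, type=ftype, qualifiers=qualifiers))
    SeqIO.write([seqrec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> AlignmentMatrix:
    """Read an aligned FASTA file; ragged row lengths are an error."""
    path = Path(path)
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(normalize_sequence(str(rec.seq)))
    if not ids:
        raise AlignmentError(f"{path}: no FASTA records")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: ragged alignment (row lengths {sorted(lengths)})"
        )
    sites = np.array([list(r) for r in rows], dtype="<U1")
    return AlignmentMatrix(ids=ids, sites=sites)


def write_fasta(ids: Sequence[str], seqs: Iterable[str],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in zip(ids, seqs):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
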