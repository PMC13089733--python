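"""Codon usage of mitochondrial protein-coding genes.

Extracts codons from annotated CDS features on their coding strand, counts
them, and computes relative synonymous codon usage (RSCU) and amino-acid
composition under a selectable genetic code — by default NCBI translation
table 9, the echinoderm/flatworm mitochondrial code, whose departures from
the standard code are AAA→Asn, AGA/AGG→Ser, TGA→Trp, leaving TAA and TAG
as the only stops.

RSCU(c) for a codon c of amino acid a with synonymous family size n_a is
count(c) divided by the mean count over the family, so an unbiased family
has RSCU 1 for every member and each used family's RSCU values sum to n_a.
Synonymous families are full amino-acid families (under table 9 Ser is
8-fold, TCN plus AGN; Leu is 6-fold); sub-family labels like "Ser1" are
display metadata only.  Stop codons are excluded from counts and RSCU, the
CodonW convention; incomplete terminal codons (a trailing T or TA completed
to TAA by polyadenylation) are returned as fragments, never counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .errors import MitostructError, ValidationError
from .genome_io import GeneFeature, MitogenomeRecord

_BASES = "TCAG"
# Standard-code (table 1) amino acids in TCAG codon order: the i-th letter
# is the product of codon (b1, b2, b3) with i = 16*b1 + 4*b2 + b3.
_TABLE1_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

#: per-table overrides of the standard code, and allowed start codons
_TABLE_DIFFS: dict[int, dict[str, str]] = {
    1: {},
    2: {"AGA": "*", "AGG": "*", "ATA": "M", "TGA": "W"},   # vertebrate mito
    5: {"AGA": "S", "AGG": "S", "ATA": "M", "TGA": "W"},   # invertebrate mito
    9: {"AAA": "N", "AGA": "S", "AGG": "S", "TGA": "W"},   # echinoderm/flatworm mito
}
_TABLE_STARTS: dict[int, frozenset[str]] = {
    1: frozenset({"TTG", "CTG", "ATG"}),
    2: frozenset({"ATT", "ATC", "ATA", "ATG", "GTG"}),
    5: frozenset({"TTG", "ATT", "ATC", "ATA", "ATG", "GTG"}),
    9: frozenset({"ATG", "GTG"}),
}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Stop",
}


@dataclass(frozen=True)
class GeneticCode:
    table_id: int
    codon_map: dict[str, str]          # 64 codons -> 1-letter AA or '*'
    start_codons: frozenset[str]

    @property
    def stops(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_map.items() if a == "*")

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_map.items() if a != "*")

    @property
    def family(self) -> dict[str, frozenset[str]]:
        """Amino acid -> its full synonymous codon family."""
        fam: dict[str, set[str]] = {}
        for codon, aa in self.codon_map.items():
            if aa != "*":
                fam.setdefault(aa, set()).add(codon)
        return {aa: frozenset(cs) for aa, cs in fam.items()}

    def translate(self, codons: list[str]) -> str:
        return "".join(self.codon_map[c] for c in codons)


def load_genetic_code(table_id: int = 9) -> GeneticCode:
    """Translation tables 1, 2, 5 and 9; others are rejected."""
    if table_id not in _TABLE_DIFFS:
        raise MitostructError(
            f"translation table {table_id} not supported "
            f"(available: {sorted(_TABLE_DIFFS)})"
        )
    codon_map = {}
    for i, b1 in enumerate(_BASES):
        for j, b2 in enumerate(_BASES):
            for k, b3 in enumerate(_BASES):
                codon_map[b1 + b2 + b3] = _TABLE1_AA[16 * i + 4 * j + k]
    codon_map.update(_TABLE_DIFFS[table_id])
    return GeneticCode(table_id=table_id, codon_map=codon_map,
                       start_codons=_TABLE_STARTS[table_id])


@dataclass
class CodonExtraction:
    """Codons of one CDS, read on its coding strand."""

    feature: GeneFeature
    codons: list[str]                  # all complete triplets, in order
    remainder: str                     # trailing 1-2 bp fragment ("" if none)
    start_codon_ok: bool = True
    terminal_stop: str | None = None   # complete stop, removed from coding codons
    internal_stop_positions: list[int] = field(default_factory=list)

    @property
    def coding_codons(self) -> list[str]:
        """Codons contributing to usage counts (terminal stop excluded)."""
        if self.terminal_stop is not None:
            return self.codons[:-1]
        return self.codons

    @property
    def incomplete_stop(self) -> str | None:
        """Padded display form of a 1-2 bp terminal fragment, e.g. 'T--'."""
        return self.remainder + "-" * (3 - len(self.remainder)) \
            if self.remainder else None


def extract_codons(record: MitogenomeRecord, feature: GeneFeature,
                   code: GeneticCode | None = None) -> CodonExtraction:
    """Split a CDS into triplets on its coding strand.

    Minus-strand features are reverse-complemented first; a trailing 1-2 bp
    remainder is an incomplete stop fragment, not a codon.  The first codon
    is audited against the code's start codons and internal stops are
    reported as a warning with positions — both are annotation red flags,
    not fatal errors.
    """
    code = code or load_genetic_code(9)
    if feature.kind != "PCG":
        raise ValidationError(f"{feature.name} is not a protein-coding gene")
    chunk = record.feature_slice(feature)
    if len(chunk) < 6:
        raise ValidationError(f"{feature.name}: CDS shorter than 6 bp")
    if feature.strand == "-":
        chunk = str(Seq(chunk).reverse_complement())
    n_full = len(chunk) // 3
    codons = [chunk[3 * i:3 * i + 3] for i in range(n_full)]
    remainder = chunk[3 * n_full:]

    extraction = CodonExtraction(feature=feature, codons=codons,
                                 remainder=remainder)
    extraction.start_codon_ok = codons[0] in code.start_codons
    if not extraction.start_codon_ok:
        warnings.warn(f"{feature.name}: first codon {codons[0]} is not a "
                      f"table-{code.table_id} start codon", stacklevel=2)
    if not remainder and codons[-1] in code.stops:
        extraction.terminal_stop = codons[-1]
    internal = [i for i, c in enumerate(extraction.coding_codons[1:], start=1)
                if c in code.stops]
    if internal:
        extraction.internal_stop_positions = internal
        warnings.warn(
            f"{feature.name}: internal stop codon(s) at codon "
            f"position(s) {internal}", stacklevel=2,
        )
    return extraction


def count_codons(extractions: list[CodonExtraction],
                 code: GeneticCode) -> tuple[dict[str, int], int]:
    """Pooled sense-codon counts; returns (counts, n_ambiguous_skipped)."""
    counts = {c: 0 for c in sorted(code.sense_codons)}
    skipped = 0
    for ex in extractions:
        for codon in ex.coding_codons:
            if "N" in codon:
                skipped += 1
            elif codon in counts:
                counts[codon] += 1
            else:   # residual in-frame stop: counted nowhere
                skipped += 1
    return counts, skipped


def rscu(counts: dict[str, int], code: GeneticCode) -> dict[str, float]:
    """RSCU(c) = count(c) / mean count over c's synonymous family.

    Families with zero total usage get ``nan`` (undefined, never 0).
    """
    values: dict[str, float] = {}
    for aa, fam in code.family.items():
        total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            values[c] = (counts.get(c, 0) * len(fam) / total) if total \
                else float("nan")
    return values


def amino_acid_composition(counts: dict[str, int],
                           code: GeneticCode) -> dict[str, float]:
    """Percentage of each amino acid among all counted sense codons."""
    aa_counts: dict[str, int] = {}
    for codon, n in counts.items():
        aa = code.codon_map[codon]
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    total = sum(aa_counts.values())
    if total == 0:
        raise ValidationError("no codons counted")
    return {aa: 100.0 * n / total for aa, n in sorted(aa_counts.items())}


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    rscu: dict[str, float]
    aa_counts: dict[str, int]
    aa_pct: dict[str, float]
    n_codons_used: int
    n_ambiguous_skipped: int
    extractions: list[CodonExtraction]

    def as_frame(self, code: GeneticCode) -> pd.DataFrame:
        rows = [
            {"codon": c, "amino_acid": AA3[code.codon_map[c]],
             "count": self.counts[c], "rscu": self.rscu[c]}
            for c in sorted(self.counts)
        ]
        return pd.DataFrame(rows)

    def audit_frame(self) -> pd.DataFrame:
        """Start/stop audit, one row per CDS."""
        rows = []
        for ex in self.extractions:
            rows.append({
                "gene": ex.feature.name,
                "start_codon": ex.codons[0],
                "start_ok": ex.start_codon_ok,
                "stop": ex.terminal_stop or ex.incomplete_stop or "none",
                "internal_stops": len(ex.internal_stop_positions),
            })
        return pd.DataFrame(rows)


def codon_report(record: MitogenomeRecord,
                 code: GeneticCode | None = None) -> CodonUsageTable:
    """Aggregate codon usage over every protein-coding gene of a record."""
    code = code or load_genetic_code(9)
    pcgs = [f for f in record.features if f.kind == "PCG"]
    if not pcgs:
        raise ValidationError(f"record {record.id} has no protein-coding genes")
    extractions = [extract_codons(record, f, code) for f in pcgs]
    counts, skipped = count_codons(extractions, code)
    aa_pct = amino_acid_composition(counts, code)
    aa_counts: dict[str, int] = {}
    for codon, n in counts.items():
        aa = code.codon_map[codon]
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    return CodonUsageTable(
        counts=counts,
        rscu=rscu(counts, code),
        aa_counts=aa_counts,
        aa_pct=aa_pct,
        n_codons_used=sum(1 for n in counts.values() if n > 0),
        n_ambiguous_skipped=skipped,
        extractions=extractions,
    )


def audit_trna_identity(record: MitogenomeRecord,
                        code: GeneticCode | None = None) -> list[str]:
    """Cross-check each tRNA's name against its annotated anticodon.

    The anticodon (RNA alphabet) is reverse-complemented to the codon it
    decodes and translated; a mismatch with the amino acid implied by the
    trnX label (e.g. a 'trnL' carrying the isoleucine anticodon GAU) is
    returned as a warning string.
    """
    code = code or load_genetic_code(9)
    messages = []
    for f in record.features:
        if f.kind != "tRNA" or not f.anticodon:
            continue
        anticodon_dna = f.anticodon.upper().replace("U", "T")
        decoded = code.codon_map.get(
            str(Seq(anticodon_dna).reverse_complement()))
        if decoded is None:
            continue
        # trnL1 / trnS2 / trnK -> one-letter amino acid label
        implied = f.name[3:].rstrip("0123456789").upper() or None
        if implied in AA3 and implied != decoded:
            messages.append(
                f"{f.name}@{f.start}: anticodon {f.anticodon} decodes to "
                f"{AA3[decoded]} but the name implies {AA3.get(implied, implied)}"
            )
    return messages
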