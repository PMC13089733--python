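"""Seeded synthetic data with exact, closed-form truth.

Two generators make every pipeline stage testable without downloads:

* :func:`simulate_mitogenome` — an annotated circular mitogenome built from
  an explicit plan (gene order, per-feature lengths, signed gap vector,
  per-feature base-composition weights).  Protein-coding genes carry a
  valid start codon, no internal stops, and a complete (TAA/TAG) or
  incomplete (T/TA) stop under the echinoderm/flatworm code.  Overlaps are
  realized by coordinate arithmetic — the downstream feature simply starts
  inside the upstream one.  When the downstream feature of an overlap is
  itself a CDS it owns the shared bases, and its codons are
  rejection-sampled until every upstream CDS still reads through without
  internal stops and with its stop codon intact, the same double-duty the
  real atp8/atp6 junction performs.

* :func:`simulate_haplotypes` — a haplotype alignment produced by planting
  substitutions on a reference row (infinite-sites by default), with H, Hd,
  S, k and Pi derived from the plan in exact rational arithmetic.

Each generator consumes its own named substream of the single integer
seed, so adding one never perturbs the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np

from .codon_usage import GeneticCode, load_genetic_code
from .diversity import DiversityIndices, haplotype_diversity
from .errors import SpecError
from .genome_io import (AlignmentMatrix, GeneFeature, MitogenomeRecord,
                        write_fasta, write_gene_table, write_genbank)

_ACGT = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

#: anticodons (RNA alphabet) assigned to generated tRNAs by name
DEFAULT_ANTICODONS = {
    "trnR": "UCG", "trnK": "CUU", "trnS2": "UGA", "trnH": "GUG",
    "trnS1": "GCU", "trnF": "GAA", "trnE": "UUC", "trnT": "UGU",
    "trnP": "UGG", "trnQ": "UUG", "trnN": "GUU", "trnL1": "UAG",
    "trnA": "UGC", "trnW": "UCA", "trnC": "GCA", "trnV": "UAC",
    "trnM": "CAU", "trnD": "GUC", "trnY": "GUA", "trnG": "UCC",
    "trnL2": "UAA", "trnI": "GAU",
}

#: genome-wide default weights over (A, C, G, T): the AT-rich, C-over-G
#: composition typical of a holothurian mitogenome plus strand.
DEFAULT_WEIGHTS = (0.341, 0.259, 0.149, 0.251)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeSpec:
    """Plan for one synthetic annotated mitogenome.

    ``genes`` lists (name, kind, strand) in genomic order; ``length_plan``
    gives each feature's length in bp; ``gap_plan`` the signed gap before
    each feature after the first (positive spacer / negative overlap);
    ``control_region`` the unannotated bp closing the circle.
    """

    genes: list[tuple[str, str, str]]
    length_plan: list[int]
    gap_plan: list[int]
    control_region: int = 151
    composition_weights: dict[str, tuple[float, float, float, float]] = \
        field(default_factory=dict)
    seed: int = 0
    label: str = "synthetic-mitogenome"

    def weights_for(self, name: str) -> tuple[float, ...]:
        return self.composition_weights.get(
            name, self.composition_weights.get("default", DEFAULT_WEIGHTS))

    def validate(self) -> None:
        n = len(self.genes)
        if n == 0:
            raise SpecError("empty gene list")
        if len(self.length_plan) != n or len(self.gap_plan) != n - 1:
            raise SpecError("length_plan must have one entry per gene and "
                            "gap_plan one per adjacent pair")
        if any(l < 1 for l in self.length_plan):
            raise SpecError("feature lengths must be >= 1")
        for i, gap in enumerate(self.gap_plan):
            if gap < 0 and -gap >= min(self.length_plan[i],
                                       self.length_plan[i + 1]):
                raise SpecError(
                    f"overlap {gap} at pair {i} exceeds a feature length"
                )
        if self.control_region < 0:
            raise SpecError("control_region must be >= 0")
        for (name, kind, strand), length in zip(self.genes, self.length_plan):
            if kind == "PCG" and length < 6:
                raise SpecError(f"{name}: CDS length must be >= 6")
            if strand not in "+-":
                raise SpecError(f"{name}: bad strand {strand!r}")


@dataclass
class SimulatedGenome:
    record: MitogenomeRecord
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit GenBank + gene-table TSV + truth JSON; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genbank": out / f"{self.record.id}.gb",
            "gene_table": out / f"{self.record.id}.tsv",
            "truth": out / f"{self.record.id}.truth.json",
        }
        write_genbank(self.record, paths["genbank"])
        write_gene_table(self.record, paths["gene_table"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1))
        return paths


class _AttemptFailed(Exception):
    pass


def _draw_codons(rng, length: int, code: GeneticCode,
                 weights: tuple[float, ...]) -> tuple[list[str], str, str, str]:
    """(codons, remainder, start_codon, stop_codon) for one CDS plan."""
    sense = sorted(code.sense_codons)
    w = dict(zip("ACGT", weights))
    probs = np.array([w[c[0]] * w[c[1]] * w[c[2]] for c in sense])
    probs /= probs.sum()
    n_full, rem = divmod(length, 3)
    codons = ["ATG"]
    n_middle = n_full - 1 - (1 if rem == 0 else 0)
    codons += list(rng.choice(sense, size=n_middle, p=probs))
    if rem == 0:
        stop = str(rng.choice(["TAA", "TAG"]))
        codons.append(stop)
        remainder = ""
    else:
        stop = "T" if rem == 1 else "TA"
        remainder = stop
    return codons, remainder, "ATG", stop


def _pcg_valid(seq: str, start: int, end: int, strand: str,
               stop_codon: str, code: GeneticCode) -> bool:
    """Does the CDS at [start, end] still read cleanly on its strand?"""
    chunk = seq[start - 1:end]
    if strand == "-":
        chunk = _revcomp(chunk)
    n_full, rem = divmod(len(chunk), 3)
    codons = [chunk[3 * i:3 * i + 3] for i in range(n_full)]
    if codons[0] not in code.start_codons:
        return False
    if rem == 0:
        if codons[-1] not in code.stops:
            return False
        body = codons[1:-1]
    else:
        if chunk[3 * n_full:] != stop_codon:
            return False
        body = codons[1:]
    return not any(c in code.stops for c in body)


def simulate_mitogenome(spec: GenomeSpec,
                        code: GeneticCode | None = None) -> SimulatedGenome:
    """Assemble the planned genome; deterministic for a given spec seed."""
    spec.validate()
    code = code or load_genetic_code(9)

    starts, ends = [1], [spec.length_plan[0]]
    for i in range(1, len(spec.genes)):
        start = ends[-1] + spec.gap_plan[i - 1] + 1
        if start < 1:
            raise SpecError(f"feature {i} would start before position 1")
        if start <= starts[-1]:
            raise SpecError(f"feature {i} would nest inside its predecessor")
        starts.append(start)
        ends.append(start + spec.length_plan[i] - 1)
    genome_length = ends[-1] + spec.control_region

    for attempt in range(64):
        rng = np.random.default_rng([spec.seed, 0x6D69, attempt])
        try:
            seq = _assemble(spec, code, rng, starts, ends, genome_length)
            break
        except _AttemptFailed:
            continue
    else:
        raise SpecError(
            "could not satisfy all coding constraints in 64 attempts; the "
            "overlap plan is too tight for valid reading frames"
        )

    features = []
    for (name, kind, strand), start, end, length in zip(
            spec.genes, starts, ends, spec.length_plan):
        start_codon = stop_codon = None
        if kind == "PCG":
            chunk = seq[start - 1:end]
            if strand == "-":
                chunk = _revcomp(chunk)
            rem = length % 3
            start_codon = chunk[:3]
            stop_codon = chunk[-3:] if rem == 0 else chunk[3 * (length // 3):]
        features.append(GeneFeature(
            name=name, kind=kind, start=start, end=end, strand=strand,
            anticodon=DEFAULT_ANTICODONS.get(name) if kind == "tRNA" else None,
            start_codon=start_codon, stop_codon=stop_codon,
        ))

    record = MitogenomeRecord(id=spec.label, length=genome_length,
                              circular=True, sequence=seq, features=features)

    truth: dict = {
        "genome_length": genome_length,
        "gap_vector": list(spec.gap_plan),
        "control_region": spec.control_region,
        "gene_order": [[n, s] for n, _, s in spec.genes],
        "features": {},
    }
    for f in features:
        chunk = record.feature_slice(f)
        entry: dict = {
            "start": f.start, "end": f.end, "strand": f.strand,
            "length": f.end - f.start + 1,
            "base_counts": {b: chunk.count(b) for b in "ACGT"},
        }
        if f.kind == "PCG":
            coding = chunk if f.strand == "+" else _revcomp(chunk)
            n_full, rem = divmod(len(coding), 3)
            codons = [coding[3 * i:3 * i + 3] for i in range(n_full)]
            if rem == 0:
                codons = codons[:-1]        # terminal complete stop
            counts: dict[str, int] = {}
            for c in codons:
                counts[c] = counts.get(c, 0) + 1
            entry["codon_counts"] = counts
            entry["peptide"] = code.translate(codons)
            entry["stop"] = f.stop_codon
        truth["features"][f"{f.name}@{f.start}"] = entry
    return SimulatedGenome(record=record, truth=truth)


def _assemble(spec: GenomeSpec, code: GeneticCode, rng, starts, ends,
              genome_length: int) -> str:
    seq = rng.choice(_ACGT, size=genome_length,
                     p=np.array(spec.weights_for("default"))
                     / sum(spec.weights_for("default")))
    written = np.zeros(genome_length, dtype=bool)
    placed_pcgs: list[tuple[int, int, str, str]] = []

    for (name, kind, strand), start, end in zip(spec.genes, starts, ends):
        sl = slice(start - 1, end)
        if kind != "PCG":
            weights = np.array(spec.weights_for(name), dtype=float)
            draw = rng.choice(_ACGT, size=end - start + 1,
                              p=weights / weights.sum())
            keep = written[sl]
            seq[sl] = np.where(keep, seq[sl], draw)
            written[sl] = True
            continue

        length = end - start + 1
        overlapped = [p for p in placed_pcgs if p[1] >= start]
        for _try in range(256):
            codons, remainder, _, stop = _draw_codons(
                rng, length, code, spec.weights_for(name))
            nt = "".join(codons) + remainder
            if strand == "-":
                nt = _revcomp(nt)
            snapshot = seq[sl].copy()
            seq[sl] = list(nt)
            if not overlapped:
                break
            text = "".join(seq)
            if all(_pcg_valid(text, s0, e0, st0, sc0, code)
                   for s0, e0, st0, sc0 in overlapped):
                break
            seq[sl] = snapshot
        else:
            raise _AttemptFailed
        written[sl] = True
        placed_pcgs.append((start, end, strand, stop))
    return "".join(seq)


# ---------------------------------------------------------------------------
# haplotype alignments
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSpec:
    """Plan for a haplotype alignment.

    ``class_sizes[0]`` is the reference class (no mutations);
    ``mutation_plan[i]`` maps site index (0-based) → substitute base for
    class ``i + 1``.  Under the default infinite-sites regime every planted
    site is used by exactly one class, so S equals the total number of
    planted sites; ``allow_recurrent=True`` lifts that restriction for
    stress tests.
    """

    n: int
    L: int
    class_sizes: list[int]
    mutation_plan: list[dict[int, str]]
    seed: int = 0
    allow_recurrent: bool = False
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def validate(self) -> None:
        if sum(self.class_sizes) != self.n:
            raise SpecError("class sizes must sum to n")
        if any(c < 1 for c in self.class_sizes):
            raise SpecError("every haplotype class needs >= 1 member")
        if len(self.mutation_plan) != len(self.class_sizes) - 1:
            raise SpecError("one mutation set per non-reference class")
        seen: set[int] = set()
        for plan in self.mutation_plan:
            for site, base in plan.items():
                if not 0 <= site < self.L:
                    raise SpecError(f"site {site} outside alignment of "
                                    f"length {self.L}")
                if base not in "ACGT":
                    raise SpecError(f"bad substitute base {base!r}")
                if not self.allow_recurrent and site in seen:
                    raise SpecError(
                        f"site {site} reused across classes; set "
                        "allow_recurrent=True to permit recurrent hits"
                    )
                seen.add(site)


def _plan_truth(spec: HaplotypeSpec) -> DiversityIndices:
    """Exact indices implied by the plan (no sequences needed)."""
    plans = [dict()] + [dict(p) for p in spec.mutation_plan]
    # merge classes whose mutation sets are identical (identical rows)
    merged: dict[tuple, int] = {}
    for plan, size in zip(plans, spec.class_sizes):
        key = tuple(sorted(plan.items()))
        merged[key] = merged.get(key, 0) + size
    sizes = list(merged.values())
    keys = [dict(k) for k in merged]

    all_sites = sorted({s for p in keys for s in p})
    S = 0
    for site in all_sites:
        states = {p.get(site, "ref") for p in keys}
        if len(states) > 1:
            S += 1

    total_diff = 0
    for (pi, si), (pj, sj) in combinations(zip(keys, sizes), 2):
        d = sum(1 for site in set(pi) | set(pj)
                if pi.get(site, "ref") != pj.get(site, "ref"))
        total_diff += d * si * sj
    k = Fraction(total_diff, comb(spec.n, 2)) if spec.n >= 2 else Fraction(0)
    pi_val = k / spec.L
    return DiversityIndices(
        n=spec.n, L=spec.L, H=len(sizes),
        Hd=haplotype_diversity(sizes, spec.n) if spec.n >= 2 else 0.0,
        S=S, k=float(k), Pi=float(pi_val), d_within=float(pi_val),
    )


def simulate_haplotypes(spec: HaplotypeSpec
                        ) -> tuple[AlignmentMatrix, DiversityIndices]:
    """Replicate a random reference row per class and plant the planned
    substitutions.  The reference base at a planted site is drawn to differ
    from the substitute, so every planned mutation is a real difference and
    the closed-form truth is exact."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0x6861])
    w = np.array(spec.weights, dtype=float)
    ref = rng.choice(_ACGT, size=spec.L, p=w / w.sum())
    for plan in spec.mutation_plan:
        for site, base in plan.items():
            if ref[site] == base:
                ref[site] = "ACGT"[("ACGT".index(base) + 1) % 4]
    rows, ids = [], []
    plans = [dict()] + [dict(p) for p in spec.mutation_plan]
    member = 0
    for idx, (plan, size) in enumerate(zip(plans, spec.class_sizes)):
        row = ref.copy()
        for site, base in plan.items():
            row[site] = base
        for _ in range(size):
            member += 1
            rows.append(row.copy())
            ids.append(f"hap{idx}_ind{member}")
    aln = AlignmentMatrix(ids=ids, sites=np.array(rows))
    return aln, _plan_truth(spec)


def random_haplotype_spec(seed: int, n_max: int = 30, L_max: int = 800
                          ) -> HaplotypeSpec:
    """A random but always-valid infinite-sites haplotype plan; used for
    bulk parameter-recovery checks."""
    rng = np.random.default_rng([seed, 0x7370])
    n = int(rng.integers(4, n_max + 1))
    L = int(rng.integers(50, L_max + 1))
    n_classes = int(rng.integers(2, min(n, 8) + 1))
    sizes = np.ones(n_classes, dtype=int)
    for _ in range(n - n_classes):
        sizes[rng.integers(n_classes)] += 1
    max_sites = min(L // 2, 40)
    n_sites = int(rng.integers(n_classes - 1, max_sites + 1))
    sites = rng.choice(L, size=n_sites, replace=False)
    plans: list[dict[int, str]] = [dict() for _ in range(n_classes - 1)]
    for pos, site in enumerate(sites):
        target = plans[pos % (n_classes - 1)]
        target[int(site)] = "ACGT"[int(rng.integers(4))]
    return HaplotypeSpec(n=n, L=L, class_sizes=[int(s) for s in sizes],
                         mutation_plan=plans, seed=seed)


def reference_like_genome_spec(seed: int = 0) -> GenomeSpec:
    """A genome plan copying the published *H. atra* architecture: same
    gene order, lengths and signed gap vector, with a 151 bp unannotated
    control region closing the circle."""
    from .genome_io import load_reference_record

    ref = load_reference_record()
    genes = [(f.name, f.kind, f.strand) for f in ref.features]
    lengths = [f.end - f.start + 1 for f in ref.features]
    gaps = [nxt.start - prev.end - 1
            for prev, nxt in zip(ref.features, ref.features[1:])]
    control = ref.length - max(f.end for f in ref.features)
    return GenomeSpec(genes=genes, length_plan=lengths, gap_plan=gaps,
                      control_region=control, seed=seed,
                      label="synthetic-h-atra-like")
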