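# mitostruct

Structural characterization of annotated mitochondrial genomes, built
around the complete mitogenome of the sea cucumber *Holothuria atra*
(GenBank PV998923; 15,788 bp, 13 protein-coding genes, 22 tRNAs, 2 rRNAs).
It is aimed at researchers describing a newly assembled invertebrate
mitogenome who need the standard descriptive battery — gene geometry,
strand-bias statistics, codon usage, population diversity indices and
gene-order comparison — as reproducible, tested code rather than a chain
of GUI tools.

## What it computes

**Gene-table geometry.** From 1-based inclusive coordinates alone:
feature lengths (wrap-aware on circular genomes), the signed gap between
adjacent genes (`start_next − end_prev − 1`; positive = intergenic spacer,
negative = overlap), a four-way overlap typology (opposite-strand,
stop-codon, CDS–CDS, other, applied in that priority), strand tallies, and
the unannotated origin-spanning stretch (putative control region).

**Composition and skew.** Base counts, percentages, and the strand
asymmetry statistics

    AT-skew = (A − T) / (A + T)        GC-skew = (G − C) / (G + C)

per feature (plus-strand slice by convention) and genome-wide.

**Codon usage.** Codon extraction from CDS features on their coding
strand — incomplete terminal stops (T / TA, completed by polyadenylation)
are handled — plus relative synonymous codon usage

    RSCU(c) = count(c) / mean count over c's synonymous family

and amino-acid composition, under NCBI translation table 9 (the
echinoderm/flatworm mitochondrial code: AAA→Asn, AGA/AGG→Ser, TGA→Trp;
stops TAA/TAG). Tables 1, 2 and 5 are also available.

**Diversity indices.** The DnaSP-style panel for a FASTA alignment:
haplotypes H, Nei's unbiased haplotype diversity
Hd = n/(n−1)·(1 − Σ pᵢ²), segregating sites S, mean pairwise differences
k, nucleotide diversity π = k/L, within-group p-distance. Complete
deletion of gapped/ambiguous columns by default; exact rational
arithmetic internally.

**Gene-order comparison.** Signed circular gene orders anchored at cox1,
breakpoint distance on canonical adjacencies (a circle and its mirrored
reading are one arrangement), arrangement-class grouping, and a
single-event classifier (single-gene translocation, segment inversion,
multi-gene shift) whose output is verified by replay.

**Synthetic data.** Seeded generators produce (a) annotated circular
mitogenomes with a planned gene order, gap vector, composition weights
and table-9-valid coding sequences, and (b) haplotype alignments with
planted mutations — both with exact truth sidecars, so every stage above
is testable without downloads.

## Worked example

```
$ mitostruct characterize \
      --gene-table src/mitostruct/data/h_atra_gene_table.tsv \
      --out-dir out
WARNING mitostruct: tRNA identity: trnL@13133: anticodon GAU decodes to Ile but the name implies Leu
INFO mitostruct: 18 spacers, 7 overlaps; outputs in out
```

`out/summary.json` then contains

```json
{
 "n_spacers": 18,
 "n_overlaps": 7,
 "max_spacer": ["trnT->trnP", 446],
 "max_overlap": ["atp8->atp6", -7],
 "wraparound_unannotated": 151,
 "strand_counts": {"PCG": {"+": 12, "-": 1},
                   "tRNA": {"+": 17, "-": 5},
                   "rRNA": {"+": 2, "-": 0}},
 "overlap_type_counts": {"opposite_strand": 3, "stop_codon": 0,
                         "pcg_pcg": 1, "other": 3}
}
```

(whitespace condensed)

i.e. 18 intergenic spacers (largest 446 bp between trnT and trnP), 7
overlaps (deepest 7 bp between atp8 and atp6), a 151 bp unannotated
control region, and 12 of the 13 protein-coding genes on the plus strand
(nad6 is the exception). The warning flags a genuine annotation quirk in
the source table: the tRNA at 13,133–13,200 is labelled trnL but carries
the isoleucine anticodon GAU.

The same library calls are available in Python:

```python
import mitostruct as ms

rec = ms.load_reference_record()
print(ms.summarize_architecture(rec).n_spacers)   # 18
print(round(ms.skew(34.1, 25.0), 3))              # 0.154 (genome AT-skew)
```

Other subcommands: `mitostruct codon-usage --genbank X.gb --table 9`,
`mitostruct diversity --fasta aln.fa`, `mitostruct order-compare
--inputs a.tsv --inputs b.tsv`, `mitostruct simulate genome|haplotypes`.
All tables are TSV with fixed column orders (composition follows
T%, C%, A%, G%, A+T%, AT-skew, GC-skew); nested summaries are JSON; every
run writes a `run_manifest.json`.

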