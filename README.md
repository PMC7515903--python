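# silkforge

Reconstruction, annotation and quantification of spider-silk (spidroin)
genes from hybrid sequencing data — with a first-class synthetic-data
generator so every stage is testable without downloads.

## The problem

Spidroin genes are long (~10 kb), spliceless, and almost entirely composed
of a tandem-repetitive domain (RTD) flanked by short non-repetitive N- and
C-terminal domains (NTD/CTD). Short-read assembly collapses the tandem
array, so contigs retain the terminals and at most a copy or two of the
repeat; the copy number and the unit consensus are simply missing. This
matters for comparative silk biology: the capture-thread proteins of
cribellate orb-weavers (cribellar spidroin CrSp and pseudoflagelliform
spidroin Pflag) differ from their ecribellate counterparts (aggregate-gland
AgSp, flagelliform Flag), while the web-frame silks (MaSp, MiSp, AcSp,
CySp, PySp) are conserved — a pattern that bears directly on whether the
orb web evolved once.

## What the package does

**Curation (`silkforge.smoc`).** Seed-and-extend reconstruction of
repetitive genes. Terminal/repeat seeds are located on contigs by
translated local alignment against family profiles. The seed's 3'-terminal
*k*-mer (*k* = 100 of 150 bp reads) recruits short reads by exact match;
their 3' overhangs are stacked into a position weight matrix and columns
are accepted while support ≥ 5 reads and dominant-base fraction ≥ 0.8.
Extension stops when trailing tandem periodicity appears — the smallest
period *p* whose trailing window (3*p* columns) matches itself shifted by
*p* at ≥ 90% identity — or when near-identical repeat copies mix in the
recruitment and column purity collapses. The repeat unit is polished by a
short-read pileup majority, and the copy number *n* is the mode over long
reads that contain NTD → repeats → CTD in order (tiling the unit between
the terminal anchors with edit-distance matching at ≥ 75% identity), which
simultaneously validates that the gene is one continuous molecule.

**Annotation (`silkforge.catalog`).** Initiation-codon choice by Kozak
context (purine at −3, G at +4) combined with a Kyte–Doolittle
signal-peptide heuristic; NTD/RTD/CTD segmentation; tandem decomposition;
and a silk-motif inventory (poly-A runs, GGX, GPGGX, GPSS, QQ/TT/SS
spacers) under a longest-motif-wins, greedy non-overlapping scan.

**Composition (`silkforge.composition`).** Repetitive-domain amino-acid
frequency vectors, their Pearson correlation matrix, and average-linkage
clustering on 1 − *r*, with a family-coherence test (do orthologs of one
family form a pure subtree before any cross-family merge?).

**Phylogeny (`silkforge.phylo`).** Terminal-domain gene trees from the
first 90 N-terminal or last 80 C-terminal residues: MAFFT alignment,
Poisson-corrected distances *d* = −ln(1 − *p*) with pairwise gap deletion,
neighbor joining with a deterministic tie-break, column-resampling
bootstrap, and per-family monophyly reports.

**Proteomics (`silkforge.proteomics`).** In-silico digestion (trypsin
rule: after K/R, never before P; ≤ 2 missed cleavages; carbamidomethyl-Cys
fixed, +57.02146 Da), observability filtering (charges 2–3 inside the m/z
400–1500 scan range), and protein quantification by

    emPAI = 10^(n_observed / n_observable) − 1

with distinct-sequence counting, plus per-web-region comparison tables.

**Simulation (`silkforge.genes`, `.reads`, `.webproteome`).** Gene models
for nine spidroin families with family-specific motif vocabularies and
architecture scales (CrSp: NTD > 2 kb, 1009 nt unit × 11 copies, 962 nt
CTD; AcSp: 1124 nt unit; Pflag: ~200 nt unit), 150 bp paired-end reads
with substitution errors, indel-biased ~10% error long reads, assembler-
style contig fixtures, and region-biased peptide observations. Generated
coding sequences are stop-free in every reading frame, so units whose
length is not a codon multiple still translate openly.

## Worked example

`python examples/02_curate_repetitive_gene.py` reconstructs a Pflag-like
gene (600 nt unit × 12 copies) from simulated contigs, 30× short reads and
20× noisy long reads:

```
recovered unit   : 600 nt, identity to truth 100.00%
copy number      : 12 (truth 12), long-read mode
continuity       : True (20 spanning long reads)
terminals        : NTD 504 nt, CTD 306 nt
```

The unit identity and copy number are measured against the generator's
truth table: the tandem structure that short-read assembly collapses is
fully restored. `examples/06_web_proteomics_empai.py` prints the emPAI
matrix per web part; aciniform silk (AcSp) ranks first in the
stabilimentum and the capture-thread proteins (CrSp, Pflag) are enriched
in the radius+spiral area, matching the web anatomy the simulated regions
encode.

A thin CLI mirrors the library: `forge run-all --outdir run --seed 1`
executes simulate → curate → annotate → compose → phylo → proteome with a
reproducibility manifest; per-stage subcommands and `forge curate
--contigs ... --short ... --profiles ...` are available for real inputs.

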