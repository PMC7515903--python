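# Methods

## Gene model and generator

A spidroin gene is modelled as a spliceless coding sequence
`NTD + n x unit + CTD`. Family templates fix the architecture scales:
CrSp uses a 2100 nt NTD (the unusually long cribellar terminal, > 2 kb), a
1009 nt repeat unit iterated 11 times and a 962 nt CTD; AcSp a 1124 nt
unit; Pflag a ~200 nt unit; the remaining families use ~500 nt terminals
and units in the 200–1200 nt range with 8–15 copies. Repeat units are
designed at the amino-acid level — family motifs (poly-A, GGX, GPGGX,
GPSS, QQ/TT/SS) interleaved with a family-specific residue background —
then reverse-translated.

Reverse translation uses only codons that contain no TA or TG dinucleotide
and do not end in T. Any concatenation of such codons is free of stop
codons (TAA/TAG/TGA) in *all three* frames, which is what keeps the CDS
open even though the 1009 nt CrSp unit is not a codon multiple and the
reading frame therefore shifts from copy to copy. The cost is that
residues C, M, W and Y cannot appear in generated gene bodies (the
initiator Met is prepended as a literal ATG); silk repetitive domains are
naturally depleted of these residues, and proteomics handling of Cys is
exercised on hand-written peptides in the tests instead.

Hierarchy of variation: a deterministic family ancestor (seeded by the
family name) gives all species recognisably homologous domains;
species-level divergence (default 2% substitutions) and per-copy
divergence (default 0.5%) are applied on the nucleotide level under the
same stop-proof constraint. The 0.5% default reflects the strong
within-gene homogenisation of spidroin tandem arrays; both are free
parameters of `SpidroinGeneModel`.

Read simulation: 150 bp paired-end fragments at 30x with
substitution-only errors (default 0.1%), and long reads at 20x with an
i.i.d. edit process at 10% total error, indel:substitution 4:1, half the
reads spanning a full reference. Coverage depths are package defaults (no
published values exist for the study conditions). Every introduced edit is
logged per read, so simulator audits (error rate, indel bias, coverage)
are exact bookkeeping rather than statistical estimates. Fixed seeds give
byte-identical FASTA/FASTQ/TSV.

What the generator does *not* emulate: homopolymer-specific nanopore
error profiles, quality-score structure, chimeric reads, intron-containing
genes, and assembly artefacts beyond the three contig policies (perfect /
repeat-collapse / terminal-only). Passing recovery tests therefore show
correctness of the algorithms under a clean i.i.d. error model, not
robustness to every real-data pathology.

## Curation

Seeds come from translated local alignment (BLOSUM62, all six frames) of
terminal/repeat profiles against contigs; hits need >= 60% identity over
>= 40% of the profile. Extension recruits reads containing the exact
3'-terminal k-mer of the consensus (k = 100 for 150 bp reads — "extremely
large" so that a single anchor is effectively unique within a gene; the
minimum usable overhang is read length − k = 50 nt). Overhangs are stacked
gap-free (substitution-only short-read model) into a PWM; columns are
accepted while support >= 5 reads and dominant-base fraction >= 0.8, ties
failing. On a stall the anchor is jittered up to 20 nt 5'-wards before
giving up, with overhang bases checked against the already-accepted
consensus — this rescues sampling dips in coverage without relaxing either
threshold.

Two stopping regimes exist by design. With effectively identical copies
the walk crosses into the array and trailing periodicity is detected
directly (smallest period p whose trailing 3p-column window matches itself
shifted by p at >= 90% identity, p >= 50 nt during extension); the
consensus is then truncated to exactly two copies past the repeat start
(located by a period-wise walk-back at 5% tolerance, then base-exact),
making the output independent of recruitment block boundaries. With
diverged copies, recruitment mixes reads from different copies and column
purity collapses near the first copy boundary — extension stops, and the
unit is instead read off the periodicity of the contig interval between
the terminal seed hits (assemblers leave one or two collapsed copies
there). Repeat-boundary phase is ambiguous wherever the NTD/CTD edge
coincides with unit edge bases; recovered terminals are exact up to a few
nucleotides of such phasing.

The unit consensus is polished by a short-read pileup majority: reads
aligning to the doubled unit (edlib, <= 10% divergence) vote per unit
position, folding phases. Because copy mutations are independent, the
across-copy majority converges on the ancestral unit even when the initial
consensus came from only two collapsed copies; unit identities in the
recovery experiments move from ~98.5–99.5% to ~100% with this step.

Copy number: for each long read (both strands), NTD and CTD are located by
edlib infix alignment at >= 75% identity (the nanopore-scale threshold);
between the anchors the unit is tiled left to right in 1.6-unit windows,
counting matches at >= 75% identity. The estimate is the mode over
spanning reads (ties resolved upward); a read set with no spanning read
yields the longest partial tiling flagged low-confidence. Continuity of
NTD → repeats → CTD on a single read is what rules out chimeric joins.

## Annotation

Start-codon selection scores every ATG opening an ORF of >= 50 codons by
Kozak context (purine at −3: +2; G at +4: +1; C at −1/−2: +0.5 each) plus
a signal-peptide score of the first 30 encoded residues: maximum 9-residue
sliding-window mean Kyte–Doolittle hydropathy scaled by 4.5, plus 0.3 for
a K/R in the first five residues. The heuristic is a deterministic in-repo
stand-in for signal-peptide predictors, and all candidate ATGs are
returned for audit. Motif scanning is greedy left-to-right and
non-overlapping with longest-motif precedence GPGGX > GPSS > polyA > GGX >
QQ/TT/SS; poly-A counts maximal runs >= 4 (configurable) once per run, and
spacer dipeptide runs count floor(run/2). Terminal profiles default to the
generator's family templates (computed on demand, clearly synthetic);
users supply their own curated profiles for real data.

## Composition clustering

Rows are amino-acid frequency vectors over the 20 canonical residues
(non-standard symbols excluded from the denominator). Distance is
1 − Pearson r with average linkage — the standard choice for
composition-profile heatmaps; both are configurable, and results carry the
method in their provenance. Flat groups are reported at a default cut
height of 0.5 alongside the full dendrogram, so no single cut is
over-interpreted. The family-coherence statistic (a family's rows forming
a pure dendrogram subtree) is the permutation-stable way to ask whether
orthologs group before families mix.

## Phylogeny

Terminals are sliced exactly (first 90 N-terminal / last 80 C-terminal
residues, shorter sources kept whole and flagged), aligned with MAFFT
(--auto, case-preserving). Distances use mismatch proportion over
ungapped column pairs with the Poisson correction d = −ln(1 − p), capped
at 10 for saturated pairs. Neighbor joining is the canonical algorithm
with ties broken at the lowest row-index pair, so trees are reproducible;
on additive matrices it provably recovers the generating topology, which
the test suite exercises against an independent implementation. Bootstrap
resamples alignment columns; supports are the percentage of replicate
trees containing each original bipartition. Distance/NJ stands in for
maximum-likelihood inference deliberately: the downstream claims consumed
here are topological (family monophyly) and robust to the tree method,
and an external ML program can be slotted in where branch-length accuracy
matters. Default 100 replicates for speed; 1000 by argument.

## Proteomics

The combined Lys-C + trypsin digest is modelled with the trypsin rule
alone (cleave after K/R, never before P): under the no-proline-exception
convention every Lys-C site is already a trypsin site, and the
identification search space that produced peptide lists was tryptic.
Observability uses charges {2, 3} (multiply charged ions are what CID
selects) within m/z 400–1500; z = 1 is excluded by default but
configurable. The emPAI denominator counts fully cleaved observable
peptides only — missed-cleavage forms inflate neither side — with a flag
to widen it. Distinct-sequence counting makes emPAI invariant to a
protein's repeat copy number: a deliberate property (asserted in tests),
and a real caveat for spidroins, whose enormous repetitive domains expose
few distinct peptides relative to their mass share. Variable
modifications are ignored; matching is exact.

## Orchestration

One `RunConfig` (YAML-loadable) drives simulate → curate → annotate →
compose → phylo → proteome with a single global seed. Each stage writes a
manifest (stage parameters, input checksums, package version); a rerun
with an identical manifest reuses the cached stage, and identical configs
give byte-identical outputs. Strict FASTQ parsing reports the offending
file and line. The demo configuration curates a subset of families
(default CrSp/Pflag across two species) to keep an end-to-end run in
seconds; all families are a config switch away.

## Problem sizes in tests

The recovery suite uses 20 genes with units of 200–1200 nt and 5–15
copies at 30x/20x coverage; repeat-detection and digestion oracles run on
200 and 50 random instances; NJ recovery on 100 random 6–10 taxon trees;
bootstrap monophyly on 9 families x 4 taxa at 100 replicates; composition
coherence on 20 replicates of 4 families x 6 species. These sizes exercise
every code path at the study's stated conditions while keeping the whole
suite under a minute.

## Known limitations

Short-read recruitment is exact-match and gap-free, so indel-rich short
reads (not part of the Illumina error model) would break anchoring. The
curation driver assumes one gene per contig set; paralog mixtures within
one recruitment pool are detected only via the unit-conflict check.
Extension cannot walk arrays whose copies diverge beyond the purity
threshold *and* whose contigs lack collapsed copies. The signal-peptide
heuristic is a linear score, not a trained model, and is flagged as such
in outputs.
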