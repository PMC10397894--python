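# Methods

## The screen

The package operationalises a population-genomic screen of splice signals
in a gene with sex-specific isoforms. The biological question: could SNPs
segregating in natural populations alter the splice sites whose
differential recognition produces the male and female transcripts? The
pipeline answers it in four steps: (1) derive every splice junction from a
multi-isoform gene model and classify it as shared or isoform-specific;
(2) place a fixed sequence window around each junction and extract/validate
its sequence; (3) intersect population variants with the windows and
characterise each hit (position tier, sex presence, stratified allele
frequencies); (4) compare nucleotide diversity between strata as a
background check that the sexes sample one population.

## Coordinates and junction identity

All coordinates are 1-based inclusive `[low, high]` intervals plus a
strand, matching VCF; report columns additionally render the transcript
order used in annotation tables (start > end on the reverse strand). A
junction is identified by the genomic coordinate of its **exonic edge
base** — the last exonic base for donors, the first for acceptors — never
by exon/intron ordinals, because cassette-exon skipping renumbers
downstream features between isoforms (the study gene's female intron 5 and
male intron 4 share one physical acceptor). Using the exonic edge rather
than the intronic gt/ag base is a convention; it is stated here and fixed
throughout.

Intron *i* of a transcript is the gap between exons *i* and *i + 1*; a
zero-length gap is a validation error. A cassette exon is an internal exon
of one isoform lying, together with both of its flanking introns, inside a
single intron of another isoform.

## Window geometry

Fixed by the screen design (all lengths in nt, transcript orientation):

| parameter | value | meaning |
|---|---|---|
| exonic flank | 6 | exonic bases in both donor and acceptor windows |
| intronic flank | 16 | intronic bases in both windows |
| tract | 12 | polypyrimidine tract preceding the NYag pattern |
| window | 22 | total, both kinds |

Donor windows cover the last 6 exonic + first 16 intronic bases; acceptor
windows the last 16 intronic (12 tract + 4 NYag) + first 6 exonic bases.
The NYag "N" base is **not** part of the 12-nt tract: the tract is the 12
bases preceding the 4-base pattern. Both window edges are inclusive — a
variant exactly on the exonic edge counts as a hit. Whether the NYag
positions themselves belong to the screened acceptor window is ambiguous in
the source annotation; they are included here (the 22-nt site positions
imply it), with the N position carrying the ordinary `window` tier.

Sequences are reverse-complemented for reverse-strand genes and rendered
with `/` at the exon–intron boundary. Case encodes coding status: with
coding (CDS) intervals supplied, coding bases are uppercase; without them,
exonic bases are uppercase and intronic lowercase. The packaged coding
intervals for the female transcript are annotation-accurate at every splice
window (which is what case rendering needs) but approximate in their
interior start/stop placement. Windows running off the contig edge are
truncated and flagged, never padded; non-ACGT bases are carried through
with a warning.

The acceptor tract score is the count of pyrimidines (C/T) among the 12
tract bases, reported with its signed difference from the species consensus
mean of 8.69 — a literature constant stored as configurable data, not
recomputed.

## Variant screen

Input VCFs are reduced to biallelic PASS SNP records with GT fields inside
the gene span (drop counts logged). Missing IDs are synthesised as
`"rs" + position`. Each (variant, window) hit gets:

* **tier** — `dinucleotide` for the invariant gt (donor window offsets
  6–7) or ag (acceptor offsets 14–15), `NYag_Y` for acceptor offset 13,
  `window` otherwise;
* **sex presence** — female_only / male_only / both / absent, from
  non-missing alt-carrying samples per sex; plus Fisher's exact test
  (two-sided) on the 2×2 sex × allele-count table. The test is an addition
  to the descriptive screen, clearly labelled, and never overrides the
  presence flag; it is skipped when a sex has no called samples.
* **stratified frequencies** — per (population, sex) cell, alt frequency
  `d / 2n` over called genotypes and folded MAF `min(p, 1 − p)`; cells with
  no calls are *undefined*, deliberately distinct from 0. Because "x% of
  samples carried the variant" can mean either quantity, the carrier
  fraction (samples with ≥ 1 alt allele) is reported alongside the allele
  frequency and neither is asserted as the canonical reading.

**Relevance rule.** "Splice-relevant" has no standard definition; the
package's operational rule is: a hit is relevant iff its tier is
`dinucleotide` or `NYag_Y`, **or** it is sex-specific (female_only /
male_only) with maximum per-stratum MAF ≥ a threshold (default 0.05). Both
the tier set and the threshold are configurable. Under the default rule
rare, non-sex-specific window hits — the pattern the screen actually
finds — are judged not relevant.

## Nucleotide diversity

For a window of length L covering variants v with non-missing allele count
n_v and alt count d_v:

    pi = (1/L) * sum_v 2 d_v (n_v - d_v) / (n_v (n_v - 1))

the unbiased mean pairwise difference per site. Implementation notes:
diploid genotypes enter only as allele counts (phasing irrelevant);
variants with fewer than two called alleles are skipped with a flag;
monomorphic and empty windows give 0; the denominator is the full window
length with **no accessibility mask** — masked pipelines will report higher
per-accessible-base values, a documented divergence. The window size for
the per-locus track is not fixed by the study design; default 500 bp,
configurable. Strata are compared per window (Δπ, ratio) and with a paired
t-test on window means. A t-test was chosen over a signed-rank test
deliberately: π estimates from small strata are right-skewed, and a
signed-rank test rejects for skewness alone even when the means agree,
which is not the "systematic difference" being asked about. Windows are
disjoint, so their π values are independent.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:

* **Reference** — a contig spanning the gene ± 300 bp in which every
  published 22-nt site sequence occupies its real coordinates
  (reverse-complemented for forward-strand storage), all other bases
  uniform random. To avoid materialising ~48.8 Mb of upstream chromosome,
  the FASTA records a coordinate *origin* in its description line
  (`origin=<int>`); readers in this package honour it, and a uniform
  coordinate `offset` can produce fully compact contigs (the shift is
  recorded in the header, and a matching shifted gene model is provided).
* **Cohort** — 655 samples in the published country/sex structure
  (Burkina Faso 67 F / 25 M, Cameroon 253 F / 44 M, Mayotte 12 F / 12 M,
  Equatorial Guinea 9 F, Gabon 69 F, Ghana 12 F, Guinea 40 F, Uganda
  112 F).
* **Variants** — background density 17,196 / 84,797 ≈ 0.2028 SNPs per bp
  (the reported polymorphic-site count over the gene span), positions
  uniform outside the splice windows and planted positions, panmictic
  frequencies drawn from the neutral 1/i site-frequency spectrum.
  Excluding windows from the background makes the windows carry exactly
  the planted variants, so the published hit pattern is the fixture's
  expected output. Planted defaults are the nine reported in-window SNPs:
  seven in the intron 3 acceptor window with non-specific frequencies
  1.5–10%, and the two exon-5-donor SNPs at the reported rarities
  (0.8% Burkina Faso F, 2% Burkina Faso M, 0.5% Cameroon F for
  rs48712947; 0.5% Cameroon F only for rs48712962).
* **Genotypes** — per sample Binomial(2, p_stratum) (Hardy–Weinberg),
  optional uniform missingness (default 0).

What the simulation does **not** emulate: linkage disequilibrium and
genealogical correlation (sites are independent), accessibility masks,
population structure beyond per-stratum frequencies, genotype error, and
multi-allelic or indel variation. Passing tests therefore certify the
coordinate arithmetic, the estimators and the screen logic — not robustness
to the correlation structure of real resequencing data. Realised presence
flags for very rare planted alleles (e.g. an expected single alt allele in
25 males) vary between seeds, as they would between resamplings of a real
population.

Everything is deterministic given the seed: fixture builds use separate
child seeds for the reference and the cohort, and repeated runs are
byte-identical.

## Degenerate inputs and tie-breaks

Single-exon transcripts have no junctions; terminal exons have no donor and
first exons no acceptor (requesting one is an error). A single-transcript
gene marks every junction as carried by that transcript alone.
Multiallelic records are excluded with a logged count. A diversity
comparison needs ≥ 2 windows for a p-value and returns p = 1 for identical
tracks. Strata with < 2 samples are skipped with a warning in the CLI
diversity command.

## Problem sizes

Default test and acceptance runs simulate the full 655-sample cohort over
the complete 84.8-kb locus (~17k SNPs, a few seconds), 100 replicates of
the planted-frequency recovery check, and 12 replicate simulations at
reduced density (0.03–0.05 SNPs/bp) for the sex-symmetry diversity check —
sizes chosen so the whole suite completes in well under a minute of compute
per component while keeping every estimate's sampling error far below the
assertion tolerances.

## Known limitations

* No branch-point, splicing-enhancer/silencer or probabilistic splice-site
  strength modelling (PWMs/MaxEnt) — the screen is positional.
* π is unmasked and will not numerically match accessibility-masked
  published tracks; only its qualitative between-strata behaviour is
  comparable.
* The GFF3 reader handles one gene per call (exons grouped by Parent); it
  is not a transcriptome-scale parser.
* Real-data scale statements (the 17,196 polymorphic sites, the exact
  population MAFs) come from a multi-GB population callset that this
  package deliberately does not download; the simulator reproduces their
  scale and structure, not their exact values.
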