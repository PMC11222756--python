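# Methods

This note documents the models, parameter choices, and numerical decisions
behind `lerayhap`, and what the synthetic-data tests do and do not
demonstrate about real data.

## What the simulator emulates

`simulate.default_mock_community` reproduces the design of a two-tank
aquarium experiment: three co-occurring hydrobiont species — two fish under
the vertebrate mitochondrial code (table 2) carrying 3 and 2 Leray-window
haplotypes, and a shrimp under the invertebrate code (table 5) carrying 2 —
sampled as per-haplotype individual eDNA samples plus two mixed
mock-community samples and a negative PCR control. Defaults and their
provenance:

- **Amplicon**: 313 nt, flanked by the degenerate Leray primer pair
  (mlCOIintF / jgHCO2198, inosines written as N) and twin 7-nt tags.
- **Replication**: 3 PCR replicates per sample, each with its own twin tag.
  The source design tags each *sample*; tagging each *replicate* is how
  Begum-style replicate filtering is actually wired in practice, and it is
  the only way replicate identity survives demultiplexing.
- **Depth**: 1,500 read pairs per sample by default. This is the package's
  desk-scale choice (the real run had ~10^5 per sample); it is the smallest
  depth at which every planned template comfortably clears the
  replicate-consistency filter.
- **Errors**: per-base substitution rate 0.001 at Q40 baseline, errored
  bases at Q10. Tag-jump rate 0.01 and chimera rate 0.005 per pair — both
  free parameters (no observed rates are published for the motivating run);
  values are in the range reported for twin-tagged Illumina metabarcoding.
  The negative control receives 0.1% of the mean sample depth, matching the
  observed control share of total reads.
- **Haplotypes** differ at synonymous third-codon positions (real
  intraspecific COI variation is overwhelmingly synonymous); **NUMTs**
  receive a substitution load of exactly round(d·313) positions placed
  uniformly — a nuclear copy is free of coding selection — plus optional
  deletions and a forced internal stop codon spent out of the same
  substitution budget, so the planned substitution-component p-distance is
  exact. The six default NUMTs mirror the lesion spectrum reported for this
  kind of survey: 1-nt deletions, a 1+2-nt frameshifting pair, internal
  stops at divergences 0.04–0.06, and one lesion-free 0.121-divergent copy.

What the simulator does **not** model: polymerase-specific error spectra,
quality decay along reads, PCR cycle kinetics and chimera hotspots, DNA
degradation, or abundance biases from primer mismatch. Passing tests
therefore demonstrate the *logic* of the pipeline (assignment, filtering,
discrimination thresholds) under controlled lesions, not its robustness to
every real-world noise source.

`simulate.generate_popset` builds Folmer-scale population datasets as
slices of a synthetic 516-codon reference gene: populations are separated
by fixed synonymous differences (placed inside, outside, or anywhere
relative to the Leray window), individuals carry Poisson(0.5) private
singleton variants. Placing all fixed differences outside the window
guarantees the trimmed dataset has no population structure — the
construction behind the fragment-reduction comparison.

## Demultiplexing and merging

A pair is assigned iff both observed 7-nt tags match the same replicate's
twin tag (default 0 mismatches — 7 nt leaves little headroom, and exact
matching is the conservative reading); two valid tags from different
replicates are a tag jump. Primers are matched IUPAC-aware with ≤ 2
mismatches immediately after the tag, in both orientations. Merging
reverse-complements R2, scores every overlap ≥ 20 nt by mismatch rate
(computed for all offsets at once via per-base cross-correlation), accepts
rate ≤ 0.1, prefers the lowest rate then the longest overlap, and resolves
overlap conflicts toward the higher-quality base. The merging thresholds
are this package's choices; no tool-specific values are published for the
motivating analysis.

## Denoising

Replicate consistency is the whole mechanism (no error model): within each
sample an ASV survives iff it reaches ≥ 2 copies in ≥ 2 replicates;
sequence length must fall in [300, 320] and contain only A/C/G/T. Begum's
exact thresholds for the motivating study are unpublished; these defaults
follow its common usage and are config-exposed. Filtering is monotone,
idempotent, and never creates counts; negative-control content is reported,
not subtracted.

## Classification and clustering

Identity against the reference library is matches over *all* global
alignment columns, terminal gaps included — a permissive measure matching
the intent of an empirically lowered 0.6 threshold (include every
homologous ASV, exclude non-target DNA). The published workflow then
excluded non-target ASVs by eye on an NJ tree; the reproducible surrogate
here is a p-distance ceiling to the nearest conspecific reference (default
0.25). Closed-reference clustering chains ASVs onto the seeds
(references ∪ assigned ASVs) by single-linkage within edit distance d = 1,
iterated to a fixpoint so membership equals the brute-force transitive
closure; ties go to the smallest distance, then the earliest seed.

## NUMT screening

Alignment to the species' nearest reference uses affine gap scores
(match 2, mismatch −1, open −6, extend −2): a gap pair always costs more
than the run of mismatches it could replace, so pure substitution variants
can never pick up spurious indels (an equal-cost tie that unit-cost edit
distance does not guarantee). The frameshift flag is raised as soon as any
alignment prefix has net indel length ≢ 0 (mod 3); a downstream
compensating indel does not clear it. Stops are counted on the ASV's
frame-0 translation under the species' genetic code, excluding the final
codon. Non-synonymous substitutions are counted only over codons whose
three columns align gap-free and in frame.

Decision rule, in order: lesion (frameshift or internal stop) →
*putative_numt*; distance ≥ 0.026 to the nearest reference with ≥ 1
non-synonymous change → *putative_numt*; distance ≤ 0.01 with clean frame →
*authentic*; < 5 total reads within edit distance 1 of a more abundant
sequence → *artifact*; otherwise *unresolved*. The 0.026/0.01 bands are the
empirical boundary observed between intraspecific variability and the
nearest divergent ASV cluster in the motivating data — parameters, not
constants of nature — and lesion-free ASVs between the bands are
deliberately never silently authentic. The rule is monotone in divergence.

p-distances are uncorrected with pairwise deletion of gapped/ambiguous
columns, exact internally and rounded to 3 decimals only in report tables.
NJ trees (scikit-bio) clamp negative branch lengths to zero and are
midpoint-rooted for reports; bootstrap resamples alignment columns
(default 1,000 replicates) and reports percent support for the base tree's
bipartitions.

## LULU curation

Daughters are visited in decreasing total abundance; a parent must be more
abundant, ≥ 84% similar (100·(1−p)), co-occur in ≥ 95% of the daughter's
samples, and dominate per shared sample by a min-ratio ≥ 1 (`avg`
available). Among eligible parents the one maximizing the ratio wins;
chains resolve to the final parent; merged counts are added into the
parent, so the curated grand total always equals the input. These are
LULU's published defaults (the motivating analysis printed none). Its
printed curated table appears to show unmodified parent rows; that is a
display variant, not the conservation semantics implemented here.

## Leray-window trimming

The window is fixed in reference coordinates: amino acids 130–236 of the
full translated gene, i.e. nucleotides 387..700 (313 nt) from the start
codon. Each dataset sequence is infix-aligned to the full-length reference
gene (edlib HW) and the window is back-mapped through the alignment path,
so in-frame deletions shorten the trimmed sequence (66 bp → 247 nt, 22
amino acids) and sequences not covering the window are excluded with a
report. A design alternative — translate, align proteins under BLOSUM,
back-map — was set aside: at intraspecific divergences the nucleotide
alignment is unambiguous and maps indels exactly.

Haplotypes are exact-identity classes (case-folded, strict on ambiguity
codes — the conservative, pegas-like reading); segregating sites are
counted over sequences of the modal length, since length variants are
distinct haplotypes but not column-comparable without an alignment. SNP
extraction keeps columns with ≥ 2 unambiguous A/C/G/T states and codes
other symbols as missing.

## The cluster-number estimator

Model: individuals i = 1..n carry categorical alleles at L SNP loci
(each SNP column is one locus — how the loci were coded in the motivating
analysis is unpublished; this coding is recorded as the package's choice).
K ~ uniform{1..K_max=20}; mixture weights ~ Dirichlet(1); per-cluster,
per-locus allele frequencies ~ Dirichlet(1), independent across loci and
clusters (the *uncorrelated* frequency model; the correlated model is
accepted as an enum but not implemented). Weights and frequencies are
integrated out, leaving an exchangeable partition prior
V_n(t)·∏_b Γ(n_b+1) (mixture of finite mixtures) times a product of
Dirichlet-multinomial cluster marginals.

Kernel, one move per generation:

- with probability 0.95, **collapsed Gibbs**: a uniformly chosen individual
  is reassigned with weight (n_b+1)·pred_b for each existing cluster and
  V_n(t+1)/V_n(t)·∏_l A_l^{-1} for a new one (missing genotypes simply drop
  out of the predictive);
- with probability 0.05, a **sequentially-allocated split/merge** move:
  two anchors are drawn; if they share a cluster, the cluster is split by
  sequential restricted allocation of its members to the two anchors and
  accepted by Metropolis–Hastings with the exact proposal probability; if
  they differ, the reverse allocation probability is computed and the merge
  proposed. Splits are births of new clusters, merges their deaths.

A pure birth/death scheme over *empty* components was implemented first and
abandoned: it is exact but cannot mix, because an empty component's
predictive is penalized on every locus at once, so the chain never leaves
K = 1 even with 10 fixed differences between populations. Split/merge is
the standard escape and recovers K = 1/2/3 at posterior density 1.0.

Run presets follow the source protocol: 100,000 generations (or 500,000 /
1,500,000), thinning every 100, burn-in of 200 (or 250) *sampled points* of
the thinned chain. One generation is defined as one MCMC move, which makes
the 100,000-generation preset a few seconds of compute at n ≤ 50. The
posterior is over the number of occupied clusters; modal density ≥ 0.8 is
flagged reliable, < 0.5 low-confidence (the motivating protocol's
reliability bands). An empty SNP matrix yields a point mass at K = 1 by
convention. Degenerate inputs: n < 2 raises; K_max is capped at n.

## Fragment comparison

The signed-rank test drops zero differences, average-ranks ties, and tests
the one-sided alternative "trimmed K < original K" via the positive-rank
sum W: exact enumeration of all 2^n sign patterns for n ≤ 12 nonzero
differences, otherwise the normal approximation with tie correction and
continuity correction (cross-checked against `scipy.stats.wilcoxon` in the
test suite; scipy is never the implementation). No nonzero differences →
p = 1 by convention. Product-moment correlations of K with dataset size and
sequence length round out the report.

## Problem sizes used in validation

The test suite and acceptance script run: mock communities of 9 samples ×
1,500 pairs (plus a control); two-population recovery at n = 20+20 with 10
fixed differences over 3 seeds; a 20-dataset ensemble at n = 12+12 with
placement of fixed differences alternating inside/outside the window; all
MCMC runs at the 100,000-generation preset. These sizes are the package's
desk-scale validation conditions.

## Known limitations

- The NUMT rule can only be as sharp as the reference library; a
  lesion-free NUMT inside the authentic band is undetectable by design.
- Chimeras are handled implicitly (replicate filtering, d = 1 chaining),
  not by a dedicated detector.
- The cluster model is non-spatial and ignores linkage between SNP columns
  of one haplotype; the correlated-frequency model is not implemented.
- Sequence counts, not template molecule counts, drive all abundance
  reasoning; PCR bias between templates is not modeled.
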