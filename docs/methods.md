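# Methods

## Model and rationale

Under the nearly neutral theory, weakly deleterious nonsynonymous mutations
segregate within populations but are rarely fixed between species, so the
within-species ratio Pn/Ps exceeds the between-species ratio Dn/Ds. The
deleterious fraction

    δ = 1 − (Dn·Ps)/(Ds·Pn)

is the share of nonsynonymous polymorphisms in excess of that neutral
expectation. δ = 0 when the two ratios agree; δ → 1 when nonsynonymous
polymorphism is large relative to nonsynonymous divergence. δ can be
negative (e.g., under positive selection inflating Dn); the estimator is
reported as-is and only the mutation-load helper requires δ ∈ [0, 1].

The complementary functional-score analysis treats externally computed
pathogenicity predictions as a severity axis x ∈ [0, 1]: if s(x) is the
probability that a variant of severity x survives purifying selection,
then the density of observed variants is proportional to s(x) times the
density of all potential variants, so the binned ratio
observed-proportion / potential-proportion estimates s(x) up to a
constant. An exponential a·exp(−b·x) summarizes it; b is the selection
gradient.

## Counting conventions

- **Genetic code.** All translation uses NCBI table 2 (vertebrate
  mitochondrial): TGA=Trp, ATA=Met, AGA/AGG=stop. The implementation takes
  the table from Biopython; the test suite checks all 64 codons against an
  independently hand-frozen dictionary.
- **Coordinates.** Annotations are 1-based inclusive (GenBank style),
  converted internally to 0-based offsets. Minus-strand genes are
  reverse-complemented before codon slicing; a trailing incomplete codon
  (polyadenylation-completed stop) is dropped.
- **Missing data.** Any alignment codon containing `-` or `N` in any pool
  member is excluded from counting, and masked columns are excluded from
  the effective length L (complete deletion). This is our choice; software
  that computes L differently will give slightly different π and θ.
- **Multi-difference codons.** Classified per site by majority vote over
  all minimal mutational pathways that avoid stop codons (the NG86
  convention); if every path passes through a stop, all paths are used. A
  tied vote is labelled pathway-ambiguous and counted as nonsynonymous in
  totals — conservative when the question is deleterious load.
- **Triallelic sites** produce one record per minor allele (each contrasted
  against the major-allele codon context) but count once in totals.
  Overlapping genes count a shared site once per gene in per-gene tables
  but once genome-wide (first gene in annotation order).
- **Polarization.** The minor allele is derived; at an exact 50:50 tie the
  outgroup state is ancestral where informative, otherwise the call is
  undetermined and flagged. Fixed differences are polarized with the
  outgroup state as ancestral unless an external ancestral-state call is
  supplied; where that call differs from both species' states, both
  directions are emitted and flagged, mirroring the dual-direction scoring
  practice for discordant ancestors.

## Statistics

- **Bootstrap CI for δ.** Each replicate redraws
  Pn\* ~ Binomial(Pn+Ps, Pn/(Pn+Ps)) and Dn\* ~ Binomial(Dn+Ds, Dn/(Dn+Ds))
  — exactly equivalent to resampling the class-labelled polymorphism and
  substitution lists with replacement, which is the minimal faithful
  reading of "resampling both within-species and fixed between-species
  substitutions". The CI is the 2.5th/97.5th percentile
  (closest-observation, so −∞ replicates from Pn\* = 0 rank correctly and
  never require arithmetic). Percentile rather than BCa: simple,
  transparent, and adequate at these count sizes. Measured coverage at the
  study's count magnitudes is about 93% rather than the nominal 95% —
  typical percentile-bootstrap undercoverage on discrete counts — and the
  coverage test asserts consistency with that level.
- **Fisher exact test** uses the conditional hypergeometric distribution
  with the two-sided point-probability criterion (scipy), verified in
  tests against exhaustive enumeration of margin-preserving tables.
- **Downsampling permutation test.** Primary mode draws n_target
  polymorphisms without replacement from the source pool's list and counts
  replicates with Pn\*/Ps\* at least the observed ratio, with the add-one
  correction and Ps\* = 0 counted as exceeding. Because only class labels
  matter, Pn\* is drawn directly from the hypergeometric distribution —
  identical in law, much faster. An alternative genome-subsampling mode
  (subsample genomes, recount segregating sites) is provided because the
  procedure's verbal description admits both readings; neither is asserted
  to reproduce any particular published p-value.
- **NG86 dN/dS.** Per-codon site counts weight each position by the
  fraction of its three one-step changes that are synonymous; changes to
  stop codons count as nonsynonymous (they stay in the denominator).
  Differences use the same stop-avoiding pathway averaging as
  classification; proportions get the Jukes–Cantor correction
  d = −¾·ln(1 − 4p/3), falling back to the uncorrected proportion with a
  warning at p ≥ ¾. Pairwise values are averaged over all cross pairs.
- **Selection function.** Scores are first mapped to [0, 1]
  (SNAP2: (s+100)/200). Ten equal-width bins; bins with zero potential
  mass are dropped, zero-ratio bins retained; the exponential is fitted by
  nonlinear least squares in linear space (log-linear fitting would
  discard zero-ratio bins). Adjusted r² uses n bins and 2 parameters. KDE
  (Gaussian, Silverman bandwidth) is provided for visualizing the two
  distributions but is deliberately not used for the ratio, which would
  amplify tail noise.
- **Diversity.** h uses the unbiased n/(n−1) correction; π is mean
  pairwise differences per usable site; θW = S/(a_n·L). SDs use Nei (1987)
  for h and π and the Watterson total variance for θ, and are labelled
  approximate. Microsatellite HE is Nei's unbiased estimator 2n/(2n−1)·(1−Σp²)
  per locus, averaged over loci; FIS = 1 − HO/HE per locus, averaged over
  loci with HE > 0 (no variance weighting — the simplest declared choice);
  AR(g) is the exact rarefaction expectation Σ_a[1 − C(N−N_a, g)/C(N, g)],
  with g defaulting to twice the smallest complete per-locus sample size
  across the dataset so values are comparable between populations.
  F = (HE_source − HE_derived)/HE_source uses the grand mean of the source
  (brackish-like) populations' HE as the source value.

## Synthetic data

The generator reproduces the study design the pipeline targets: pooled
freshwater n = 26 and brackish n = 31 mitogenomes, one outgroup genome, 13
protein-coding genes with lengths close to the vertebrate OXPHOS
complement (ND6 on the minus strand), per-pool polymorphism targets
(Pn, Ps) = (28, 51) and (41, 145), fixed-difference targets
(Dn, Ds) = (141, 1565), a singleton probability of 0.7 (most variants are
rare; non-singleton carrier counts are drawn up to a minor allele
frequency of 0.108), and score distributions Beta(1.2, 4) for observed vs
Beta(4, 1.5) for potential variants, with SNAP2-style scores sharing the
latent severity plus scorer noise so the two predictors correlate
imperfectly. Microsatellites drift 9 loci through a 25-diploid bottleneck
for 18 generations by default, giving an expected heterozygosity loss of
1 − (1 − 1/50)^18 ≈ 0.30, the scale of a post-glacial freshwater
colonization.

Variants are planted, not evolved: every planted variant occupies its own
codon whose one-step mutant has exactly the required effect, so classifier
recovery of the targets is exact and the end-to-end δ is deterministic.
This is the point — it makes the pipeline's bookkeeping testable — but it
also means the synthetic data lack features of real mitogenomes: no
recurrent or multi-hit mutation, no codon-usage or strand-asymmetry bias,
no gene-overlap regions, no within-pool population structure, and fixed
differences all sit on the outgroup branch. Passing planted-truth tests
therefore validates counting and inference logic, not robustness to those
real-data complications. An exponential acceptance-sampling score mode
plants a known selection gradient b for recovery tests.

All generators are pure functions of (config, seed); identical seeds give
byte-identical outputs.

## Problem sizes in the test suite

Resampling tests in the suite use 1,000–10,000 replicates and 150–400
simulation runs, and the full-scale synthetic study (1,935 planted
variants across ~11.6 kb) is built once per session; the whole suite runs
in well under a minute on one CPU.

## Known limitations

- Dn/Ds come from a single-outgroup comparison; a reconstructed ancestral
  sequence would differ at sites with multiple hits on the outgroup branch.
- Per-locus FIS averaging and the complete-deletion rule are declared
  choices; published tables computed with other conventions (e.g., DnaSP's
  site handling, FSTAT's weighting) will match only approximately.
- The mutation-load definition (δ × mean derived nonsynonymous alleles per
  genome) is declared, not canonical.
- p-values for the genome-subsampling permutation mode depend on which
  sites remain segregating in subsamples and are not exchangeable with the
  label-downsampling mode's p-values.
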