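# Methods

`embryoprot` re-implements, as a tested and reusable pipeline, the
quantitative analysis of a developmental proteome/transcriptome atlas of the
model chordate *Ciona robusta*: absolute protein quantification in the
unfertilized egg from spike-in standards, temporal profile analytics over an
eight-stage developmental series, reciprocal-best-hit (RBH) orthology against
a vertebrate (*Xenopus laevis*), cross-species stage-correspondence analysis
(the hourglass vs. inverse-hourglass question), and an in-silico digestion
check of peptide robustness to SNPs between animal batches. A synthetic-data
generator stands in for the deposited raw data so that every downstream stage
is exercised and validated without downloads.

## Absolute quantification (spike-in standard curve)

Standards of known amounts spanning several orders of magnitude (a staggered
UPS2-style set) are spiked into the egg lysate. The measured MS1 area `S`
relates to the amount `A` by a power law, a line in log space:

    log10 S = m · log10 A + b

The line is fitted with the Theil–Sen estimator — slope `m` is the median of
all pairwise slopes over pairs with distinct x, intercept `b` the median of
`y − m·x` (computed via `scipy.stats.theilslopes(method="joint")`, which
implements exactly this definition). Theil–Sen tolerates gross outliers: a
single standard corrupted by three orders of magnitude moves the slope by
less than 10% when eight standards are available. Standards with zero signal
(undetected) are excluded and counted.

Sample signals are inverted through the curve, `A = 10^((log10 S − b)/m)`,
isoform signals optionally summed per gene before conversion, and all
concentrations rescaled by one global factor so their molar sum equals the
configured total protein concentration of the egg (default 2 mM). A
low-concentration cutoff (default 0.01 µM) is applied after scaling,
following the order of operations of the protocol. Both the total and the
cutoff are configuration parameters rather than constants, because the
printed cutoff (10 nM) is not consistent with reported sub-cutoff medians
for regulatory protein classes; the module takes no position on the exact
sequence the original normalization used.

## Complex stoichiometry

Detected proteins are mapped to a catalog of stable complexes (CORUM-style
membership lists). Complexes with at least three detected subunits are
compared against the remaining proteome on log10 concentrations in two
complementary ways:

* **Dispersion (primary `p_value`)** — a one-sided variance-ratio test of
  the complex's subunit scatter against the background scatter. This is the
  quantity that "subunits of a shared complex display comparable values"
  actually measures: a mean-location contrast has essentially no power to
  detect stoichiometric tightness for complexes whose abundance sits near
  the proteome median, whereas the variance-ratio test flags a complex with
  within-complex log10 sd 0.1 against a background sd of 1.0 nearly always,
  and false-flags background-sampled null complexes at no more than the
  nominal rate.
* **Location (`tukey_p`)** — one-way ANOVA across groups followed by Tukey
  honest-significant-difference comparison of each complex against the
  background group (the protocol as printed), which detects complexes whose
  abundance level differs from the bulk proteome.

## Temporal profile analytics

All time-course matrices are first median-normalized (each stage column
rescaled so its median equals the grand median of the matrix), then each
entity's profile is scaled to sum to one across the series, making profiles
comparable across entities, modalities, and species. Sum-to-one scaling is
idempotent and preserves zeros; missing stages are excluded from the sum and
stay missing.

Profiles are clustered by Euclidean k-means, best of 100 random restarts by
total within-cluster sum of squares (defaults k = 8 within species, k = 5
for RNA–protein and cross-species ortholog co-clustering, where each
ortholog pair is represented by the concatenation of its two sum-to-one
profiles). Clustering is delegated to `sklearn.cluster.KMeans`
(`init="random"`, `n_init=restarts`, Lloyd's algorithm); sklearn's internal
empty-cluster relocation (re-seeding from high-inertia points) stands in for
an explicit farthest-point rule. Cluster ids are relabeled by descending
cluster size (ties by first-occurring entity), so the labeling is
deterministic for a given seed.

RNA–protein agreement is the per-gene Pearson correlation between the two
sum-to-one profiles over shared, non-missing stages (at least three);
zero-variance profiles are excluded and counted. Spearman and cosine
variants are available. Stage-transition ranking orders entities by
|log2 ratio| between consecutive stages with a pseudocount of half the
smallest positive value guarding zeros. Gene-level TPM is the per-stage sum
of transcript TPMs; a gene counts as expressed at TPM ≥ 2 (inclusive).

## Orthology

One-to-one orthologs are resolved from precomputed reciprocal alignment hit
tables (BLASTP `-outfmt 6` dialect; the documented aligner invocation uses
BLOSUM45, e-value 0.01, one target per query). Per query the best subject
has (1) the lowest e-value and (2) the highest bit score; remaining ties
fall to file order and are logged. A pair is kept only when best in both
directions, which makes the map one-to-one by construction. Gene-level
collapsing projects protein pairs onto genes and drops any gene matched to
two or more distinct partner genes.

## Cross-species stage correspondence

For every pair of stages (s, t) of the two species, the similarity is the
Pearson (default), Spearman, or cosine association between the vectors of
ortholog values at s and t, computed over mapped pairs present in both sets
(sum-to-one profiles, linear space; quantile normalization is available for
transcriptome matrices). The best-matching partner stage per row (ties
toward the earlier stage, logged) forms the correspondence trace;
divergence is `1 − best similarity` per stage, reported unclamped (Pearson
divergence can exceed 1).

The hourglass statistic operationalizes the visual pattern of divergence
curves, which the source analysis presents graphically without a formal
test:

    H = mean divergence(mid) − ½·(mean divergence(early) + mean divergence(late))

`H > 0` means divergence peaks at mid-development (inverse hourglass, the
pattern reported for chordate proteomes at gastrulation/neurulation);
`H < 0` means a mid-developmental conservation bottleneck (classic
hourglass). Significance comes from permuting the early/mid/late class
labels across stages (two-sided on |H|, add-one-corrected, 1000 permutations
by default); the reported `label` falls back to `flat` when p ≥ 0.05 while
`direction` always carries the sign of H. For the eight *Ciona* stages the
default class map puts unfE/fertE/cell-16 in early, iniG/latN (gastrulation
and neurulation) in mid, and midTII/latTII/larva in late; synthetic series
are split into near-equal thirds. With two mid stages out of eight the
permutation p-value cannot fall below 1/28 ≈ 0.036, which the default
alpha = 0.05 accommodates.

## In-silico digestion

Trypsin cleaves C-terminal to K or R except before proline; LysC cleaves
after K including before proline. With `m` allowed missed cleavages every
union of up to `m + 1` consecutive fully-cleaved fragments is emitted;
length filters apply last. Digestion is position-faithful: with no missed
cleavages the peptides of a protein concatenate back to the protein. The
SNP-robustness report digests the id-shared sequences of two databases and
reports shared/unique peptide fractions over the union of distinct peptide
strings (set semantics; a count-weighted mode exists). Defaults are zero
missed cleavages and no length filter, documented as an interpretation since
the source protocol does not state them.

## Synthetic data

Every generator is a pure function of its parameters and a seed (one
`numpy.random.default_rng` stream per call), hence bit-reproducible.
Abundance noise is log-normal — Gaussian in log10 space — matching the
multiplicative error of MS signal. Defaults mirror the study conditions:
eight developmental stages per species, an egg proteome spanning eight
orders of magnitude with total 2 mM, 48 spike-in standards, within-complex
log10 sd 0.1 against a background sd of 1.0, and SNP rates of ~10⁻³ per
residue.

Latent temporal programs are smooth positive curves (cubic spline through
six random control points over normalized stage time, exponentiated), so
stage autocorrelation resembles real developmental series rather than white
noise. Cross-species decorrelation mixes each ortholog's partner profile
with an independent program; the mixing weight follows a clipped quadratic
bump in normalized stage time, `w(u) = clip(effect·max(0, 1 − ((u − ½)/h)²))`
with half-width `h = 0.25`, used directly for the inverse-hourglass shape,
complemented for the hourglass shape, and held at half height for flat. The
finite half-width matters: an unclipped quadratic spreads decorrelation into
early and late stages, which makes the two-sided permutation test
structurally unable to reject (the anti-labeling with "mid" on the two end
stages then always reaches |H| at least as large as the true labeling's), so
the bump is confined to the mid window. At `effect_size = 0` all shapes
degenerate to identical, fully conserved programs.

What the generator does **not** emulate: raw spectra, chromatography,
reporter-ion interference, peptide detectability, shared peptides between
paralogs, batch effects, or compositional coupling between orthologs.
Passing tests therefore demonstrate the correctness and statistical
calibration of the analysis code under the stated noise model, not the
biological conclusions one would draw from the deposited data.

## Numerical choices and edge cases

* Expression values serialize in linear space with 10 significant digits;
  missing is `NA` (or a blank cell on input) and is distinct from zero.
* Stage order always comes from column order, never lexical sorting.
* Quantile normalization assigns tied values the mean of the reference
  values their ranks span.
* Degenerate inputs fail loudly: all-zero stage columns, all-identical
  standard amounts, empty ortholog maps, zero shared identifiers, unknown
  residues, and sub-minimum class sizes each raise a typed error.
* All dropped/excluded entities (zero signals, incomplete profiles,
  conflicting gene pairs, sub-threshold hits) are counted and logged.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: standard-curve checks use up to 48 standards and hundreds of
replicates; stoichiometry power/size uses hundreds of tight and null
complexes; shape-recovery panels use 300 orthologs by 8 + 8 stages across a
few hundred seeds; the digestion corpus is 5,000–10,000 random sequences.
These sizes were chosen to give stable Monte-Carlo estimates of the rates
they measure.

## Known limitations

* The `tukey_p` location contrast inherits the usual Tukey assumptions
  (homoscedastic groups), which the tight complexes deliberately violate;
  it is reported for completeness, not used for the tightness call.
* The hourglass permutation test is coarse for short stage series (28
  distinct mid assignments for 8 stages with 2 mid labels).
* RBH orthology consumes precomputed hit tables; the package never runs an
  aligner.
* Excel supplements of the source study are not parsed; expression matrices
  enter as TSV.
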