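# Methods

This note documents the models, defaults, and numerical choices behind
`dopamet`, and what the synthetic-data tests do and do not demonstrate about
real microarray data.

## Synthetic data model

The generator emulates a common-reference two-color design. Per tissue, a
control-pool log2-expression vector c_g ~ N(10, 1.5) sets a plausible array
dynamic range (the raw studies publish no intensity distributions; these
values are fixed once and not tuned). For each treatment, `arrays_per_pool`
(default 4) hybridizations are produced: three biological pools plus a
dye-reversal replicate of the third pool, matching the study design. The
treatment channel of pool p is

    t_pg = c_g + e_g(treatment) + N(0, pool_bio_sd),

with per-spot log2 noise N(0, `noise_sd`, default 0.25) added independently
to both channels and to each duplicate spot. `pool_bio_sd` (default 0.10)
models biological variation across pools of 2–3 animals; animals are not
simulated individually because pooling happens upstream of all computation.

Ground-truth effects encode the generative converse of the downstream
selection rule. A fraction `frac_regulated` (default 0.10) of genes is
regulated; each regulated gene draws a receptor subtype from `receptor_mix`
(default D1 0.5 / D2 0.3 / both 0.2 — D1 dominance mirrors the hypothalamic
finding) and a signed magnitude e with |e| ~ |N(effect_log2_mean,
effect_log2_sd)| (defaults 1.0, 0.0). The matching agonist gets +e, the
matching antagonist and the depletion treatment get −e x
`attenuation_blocker` (default 1.0). Unregulated genes are exactly zero.

Each array is finally distorted by an affine similarity in (log2 ch1, log2
ch2) space — rotation (default up to ±3°), isotropic scale (0.9–1.1),
translation (±0.5) about the cloud centroid. These magnitudes represent
mild scanner-gain / dye-bias technical variation; they are exactly the model
class GPA inverts, which is deliberate: the normalization stage is testable
because its inverse model is known. Real arrays also contain
intensity-dependent (curved) dye bias, print-tip effects, and spatial
artifacts that an affine model does not capture — passing tests here show
correctness of the implemented model, not that GPA suffices for every real
slide.

Determinism: all randomness flows from `rng_seed` through independent
`SeedSequence` substreams keyed by (stage, experiment, tissue, treatment),
so outputs are byte-identical across runs and insensitive to generation
order. The default seed is 20121102 and is recorded in every output header.

## GPA normalization

Arrays of one tissue-experiment batch (the hybridization unit; a flag
switches to one global fit) are aligned as n_spots x 2 point clouds:

1. translation: each cloud is centered;
2. rotation: the determinant-+1 orthogonal-Procrustes (Kabsch) solution
   against the current consensus — reflections are forbidden so the fit can
   never implicitly swap dye channels; dye reversal is resolved explicitly
   when loading (treatment channel is always column 1);
3. scale: the least-squares scales under the classical total-size constraint
   Σ‖scaled_i‖² = Σ‖centered_i‖², obtained as the dominant eigenvector of
   the normalized cross-covariance trace matrix (ten Berge); the constraint
   prevents collapse to zero;
4. consensus: the mean of the transformed clouds; iterate until the relative
   residual change falls below `tol` (default 1e-8, max 100 iterations).

Each step is a constrained minimizer, so the recorded residual history is
non-increasing; a degenerate cloud (zero size) or a batch of mutually
uncorrelated clouds (for which no strictly positive scaling exists) raises
an explicit error rather than returning a reflection-like fit.

Intensities are clipped below at `floor` (default 1.0) before log2; spots at
the floor are retained. Analyses that legitimately produce sub-unity
intensities (e.g. strong synthetic distortions) should pass a smaller floor.

**Frame conventions.** A Procrustes consensus is defined only up to a global
rotation, and a distortion shared by *every* array is indistinguishable from
data expressed in a different frame. Two anchored outputs are provided:

- `anchor="consensus"` (production): ratios are read from the centered
  aligned clouds, so each array has mean log2 ratio exactly zero. This is
  the classical balanced-changes normalization assumption; an array-wide
  mean shift (dye bias vs. global regulation) is not identifiable in a
  common-reference design, and re-introducing any estimate of it would
  propagate average dye bias into every gene. Consequently planted effects
  are recovered exactly only when they sum to zero across genes; with the
  default 10% regulated genes of random sign the induced shrinkage is
  O(Σe/n_genes) ≈ 0.01 log2 units — negligible against effects of 1.0.
- `anchor="first"`: all aligned clouds are re-expressed in the first
  configuration's input frame. When the first array is undistorted this
  inverts planted distortions exactly (observed ≈ 1e-14), which is how the
  recovery tests are constructed. Equivariance under a *common*
  pre-rotation of all inputs holds for the residual trajectory (tested
  exactly) but cannot hold for channel-difference ratios in any
  data-anchored frame; this is a property of the geometry, not of the
  implementation.

## One-class SAM

Every array is treatment vs. one common reference, so differential
expression is one-sample: d_g = x̄_g / (s_g + s₀), s_g = sd_g/√n. The fudge
factor s₀ is the percentile of the s distribution (grid 0, 5, …, 100)
minimizing the coefficient of variation of the MAD of d within 100
s-quantile windows, ties toward the smallest percentile. The null flips the
sign of whole arrays: exhaustively (2ⁿ ≤ 4096; n = 4 gives 16 exact
permutations, so results are fully reproducible) or by seeded sampling.

For every threshold Δ over the grid of distinct |d_(i) − d̄_(i)| values
(d̄ = permutation-mean order statistics), the asymmetric cut rule calls
genes with d ≥ cutup(Δ) = min{d_(i) : d_(i) − d̄_(i) ≥ Δ} or
d ≤ cutlow(Δ) = max{d_(i) : d_(i) − d̄_(i) ≤ −Δ}. The two tails are counted
as a union (they can cross for tiny gene sets). FDR(Δ) = π₀ · median
permuted count beyond the cuts / #called, with π₀ = min(1, #{d in the
central quartiles of the pooled permuted d} / (m/2)). A gene's q is the
minimum FDR over the Δs at which it is called, then made monotone by a
cumulative minimum along ascending |d| (q(g) = min estimated FDR over genes
no more significant than g — the standard q-value enforcement) and clipped
to [0, 1]. On pure-null simulations (1000 genes, n = 4) the fraction of
genes at q < 0.05 is ≲ 0.5%, i.e. conservative.

Signed fold changes follow the reported-table convention: 2^x̄ for x̄ ≥ 0,
−2^(−x̄) otherwise, so a 1.7-fold decrease prints as −1.7 and |FC| ≥ 1
always.

## Reciprocal filter and receptor attribution

Per tissue, per-treatment results are outer-joined on gene id; only cells
with q below the threshold (default 0.05) survive. Thresholding is applied
per reported cell — i.e. q < 0.05 is required of every member of a
qualifying pair, not of all five treatments, which is the only reading
consistent with the published table's sparse rows. A gene is accepted when
at least one qualifying pair exists among its significant cells:

- *reciprocal*: one agonist {SKF, LY} against one blocker {SCH, sulpiride,
  MPTP+αMPT} with opposite fold-change signs;
- *same-direction*: MPTP+αMPT with an antagonist, equal signs (both
  manipulations lower DA signaling).

Acceptance is exists-one-pair, not all-pairs-consistent: the published
table contains rows that pass through one pair while another combination
does not qualify. A fold change of exactly +1.0 (x̄ = 0) has no sign and
joins no pair. Receptor attribution takes the union of subtypes implicated
by each pair's drugs (SKF/SCH → D1, LY/sulpiride → D2; the depletion
treatment is non-selective): one subtype → that receptor, both → "both"; a
guarded "indeterminate" label exists but is unreachable under the pair
definitions. Rejected rows carry machine-readable reasons
(`single-treatment`, `non-qualifying-pattern`), and `validate-fixtures`
audits the packaged published rows the same way — one row (NSUN2: two
same-signed cells, no depletion column) satisfies neither printed rule and
is flagged rather than second-guessed.

## SNEA

Measured platform genes map to human symbols through an explicit homolog
table (unmapped entries are marked, never silently dropped; the packaged
table reproduces the published tally of 114 mapped hypothalamic genes). For
each seed regulator and relation type, the overlap of its target set with
the measured list is tested against the remaining measured genes
(two-sided Mann–Whitney, midranks, tie-corrected variance, continuity
correction). The background is the analyzed gene list, not the whole array
— the narrower, more conservative choice. Retention requires p < alpha
(0.05) and overlap strictly greater than `min_members` (5, i.e. ≥ 6).
The expression value per gene is the signed log2 fold change of one
contrast, default SKF 38393 (the agonist arm of the analyzed reciprocal
set); relation signs are carried into the edge-list export but do not enter
the rank statistic. Published enrichment p-values depend on a proprietary
full relation network and are packaged as transcription only — the fixtures
preserve the seed/entity structure, and no test asserts those p-values.

Exact mode for the U test enumerates the permutation distribution
(scipy's exact method for untied samples; an in-package midrank
enumeration, guarded to ≤ 500k assignments, when ties are present) and is
selected automatically for min(n₁, n₂) ≤ 8. The normal approximation agrees
with exact enumeration within 5% relative p in the decision-relevant regime
(p ≳ 0.05) at sizes (8, 20); in the deep tail its relative error grows, as
for any normal approximation, while remaining accurate in absolute terms —
the null retention rate of size-8 seeds stays within binomial noise of
alpha.

## qPCR

The relative standard curve fits Ct against log10 relative quantity over a
dilution series (default 1:10 then 5-fold steps to 1:31,250, the only
series consistent with the published endpoints). Efficiency
(10^(−1/slope) − 1)·100 is 100% at slope −1/log10 2 ≈ −3.32. QC gates are
hard: R² > 0.99 and efficiency in [90, 110]%; quantification refuses a
failed curve, and NTC/NoRT control wells must show no amplification.
Per-sample expression is target/reference quantity (any sample-wide
multiplicative factor cancels); groups are summarized by the arithmetic
mean (the source protocol does not specify mean vs. median) and compared
with the exact two-tailed Mann–Whitney test.

## Problem sizes and limitations

Simulation-based checks use 1000 genes, n = 4 arrays per treatment, and 20
replicate seeds — large enough for stable sensitivity/FDR estimates while
keeping the full suite fast. At the default conditions (10% regulated,
|log2 effect| 1.0, noise 0.25, attenuation 1.0) the reciprocal list attains
sensitivity 1.0 with empirical FDR ≤ 2% per seed. Known limitations: the
affine distortion model understates real spatial/intensity-dependent
artifacts; mean-zero normalization assumes balanced regulation; attenuated
blocker effects (attenuation < 1) trade sensitivity for the same FDR
control; and the packaged relation fixtures cover only the published seeds,
so enrichment results on them are structural checks, not biological
discovery.
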