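# Methods

This note documents the models, estimators and numerical choices behind
`fxsmap`, and what the synthetic data do and do not establish.

## Differential expression

Within one stratum (system × region) each gene g is modeled as a
two-group Gaussian: the effect is β̂_g = mean(KO) − mean(WT) on the log2
scale, the residual variance s²_g pools both groups on d_g = n₁ + n₂ − 2
degrees of freedom. Variance moderation follows the standard empirical-
Bayes hierarchy: s²_g | σ²_g ~ σ²_g χ²_{d_g}/d_g with a scaled inverse
chi-square prior σ²_g ~ d₀s₀²/χ²_{d₀}, giving the posterior
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and a moderated
t_g = β̂_g/√(s̃²_g(1/n₁+1/n₂)) on d₀ + d_g degrees of freedom.

(d₀, s₀²) are estimated by the method of moments on z = log s²:
E z = log σ² + ψ(d/2) − log(d/2) and Var z = ψ′(d/2) + ψ′(d₀/2), where ψ
and ψ′ are the digamma and trigamma functions. The trigamma equation is
inverted by a damped Newton iteration (tolerance 1e-8, ≤ 100 steps,
started at y = 0.5 + 1/x). When the observed spread of z does not exceed
the chi-square sampling noise — including the exactly-equal-variance
case — d₀ is infinite and every posterior variance equals s₀² (d₀ values
above 1e6 are treated the same). With fewer than 10 genes the moments
estimate is unstable, so the fit falls back to the ordinary t (d₀ = 0)
with a warning. The implementation reproduces R/Bioconductor limma
(lmFit + eBayes) to ~1e-6 relative on a frozen reference fixture.

Degenerate rows: zero posterior variance with zero effect gives t = 0,
p = 1; with nonzero effect, t = ±∞ and p is clamped to the smallest
positive double so p ∈ (0, 1] always holds. Significance is unadjusted
p < 0.05 (the pipeline's rule); Benjamini–Hochberg is available via
`select_de(..., adjust="bh")` but not used by any default path.
Technical duplicate columns are treated as independent samples by
default; `collapse_duplicates` averages them into their source columns
when the more conservative treatment is wanted.

## Landscape PCA

The whole-dataset view ranks each sample column (average ranks for ties)
and standardizes it to mean 0 / variance 1 (sample SD, ddof = 1), making
the embedding invariant to any strictly monotone per-sample distortion.
Whether to rank within samples or within genes is genuinely ambiguous;
per-sample ranking was chosen for consistency with the per-sample
standardization used on the human series, and the downstream checks
(axis assignment, centroid-gap ratios) hold under either convention.
PCA is a thin SVD of the column-centered samples × genes matrix computed
over all strata jointly; per-stratum genotype metrics are derived
afterwards. Component signs are fixed so each component's
largest-magnitude loading is positive; variance fractions are
σ²_k / Σσ²_i over all singular values. The genotype effect per stratum is
the absolute KO−WT centroid difference along PC1 and PC2.

## Enrichment statistics

Fisher exact p-values are sums of hypergeometric log-pmf terms combined
with log-sum-exp, so extreme tables do not underflow (results are clamped
into (0, 1]). The two-sided test uses the "minlike" convention: the sum
of all table probabilities ≤ the observed one (with a 1+1e-7 relative
tolerance for ties), matching `scipy.stats.fisher_exact`. The EASE score
is the one-sided Fisher p recomputed after decrementing the overlap cell
(a−1, margins shrink accordingly); a ≤ 1 scores 1. Enrichment against a
collection is one-sided at an EASE threshold of 0.1; the background
universe is always an explicit argument (whole-array vs annotated-only
backgrounds give different answers, so no silent default is offered).
Overlap odds ratios use ad/bc with the Woolf logit interval at z = 1.96;
a zero cell triggers the Haldane–Anscombe +0.5 correction for the OR and
interval only (flagged), never for the exact p.

## Developmental map

Each region's staged series is processed as: per-sample standardization →
per-gene centering → SVD → k-means (k = 3, Lloyd, best of 20 restarts,
seeded) on the first two gene scores. The per-gene centering is a
deliberate choice: without it the leading component is the per-gene
expression-level axis and the temporal contrasts are pushed to later
components, so clustering the displayed two components would group genes
by abundance instead of by trajectory. With it, noise-free archetype
fixtures produce three collinear rays in score space and clustering on
the displayed components recovers them exactly. Clustering the full
standardized stage-mean profiles instead is available via
`feature_space="profile"`.

Clusters are labeled early/mid/late by the argmax stage of their median
profile (per-stage median over member genes of stage-mean standardized
expression), ordered ascending; ties fall back to the earlier center of
mass of the min-shifted profile, and identical (argmax, center-of-mass)
pairs are rejected as degenerate. The fetal/postnatal boundary at stage 7
is not used for assignment, only as an interpretive anchor.

Projection counts mouse DE genes per cluster after homology mapping;
genes outside the common universe are dropped with a logged count.
Early-cluster over-representation uses the 2×2 table
(a = DE ∩ early, b = DE ∩ rest, c = early − a, d = rest − b) against
whole-universe cluster totals — the totals include the DE genes, the
convention that exactly reproduces the published odds ratios and CI from
the packaged per-cluster counts (`fxsmap.published`). Percentages are
rounded to integers, or one decimal where the reference tables print
decimals; both rounding modes are exposed.

## Identifier mapping

Multi-ID probes take the numerically smallest Entrez gene ID;
unannotated probes are dropped with a logged count rather than raising.
Gene-level statistics keep the probe with the smallest p-value per gene
(the chosen probe ID is retained for provenance); the developmental
series instead keeps, per gene, the probe minimizing the sum over stages
2–15 of per-stage coefficients of variation (sample SD, ddof = 1, over a
stage's samples divided by their mean; single-sample stages contribute
SD = 0 with a warning; a zero stage mean disqualifies the probe with an
infinite score). The stage window is a parameter; 2–15 is the default.
The same chosen probes are re-applied to the second region's matrix so
both regions use identical representatives. All ties (equal p, equal
coefvar sums) resolve to the smallest probe ID, making every collapse
order-invariant and idempotent. Non-integer gene IDs are accepted but
compared lexicographically with a warning.

## Synthetic data

The mouse generator emulates the reference study design: per genotype,
cortex tissue n=5, hippocampus tissue n=6, cortical culture n=5,
hippocampal culture n=5 → 42 samples; `duplicate_fraction` additionally
emits technical duplicate columns (source + fresh noise at SD ≤ σ/2).
Gene-level means are baseline N(7, 1.5²) plus hierarchical shifts:
culture-vs-tissue N(0, 2²), region N(0, 1²), and genotype effects on a
planted subset (15% of genes in culture at SD 0.6; 5% in tissue at
SD 0.15), with the first gene ("Fmr1") fixed at −1 log2 in every KO
column and residual noise N(0, 0.5²). The enforced ordering
δ_system > δ_region > δ_genotype reproduces the observed variance
hierarchy (PC1 = system, PC2 = region). Half of each planted genotype
effect (in SD terms, `genotype_alignment = 0.5`) is aligned with the
culture-vs-tissue gene axis, emulating the observed coupling between the
KO signature and the maturation axis; this is what makes the KO/WT
centroid gap visible on PC1 and, with the culture/tissue effect-size
ratio, yields a culture gap ≥ 3× the tissue gap. Per-gene marginal effect
SDs are unchanged by the alignment.

The human generator assigns each gene one of three temporal archetypes
(40/30/30): piecewise-linear curves peaking at stage 6 (early, falling
after), stage 9 (mid) and stage 12 (late, staying high), amplitude 1 log2
unit with a uniform 0.8–1.2 per-gene multiplier, over 15 stages × 2
regions × 3 samples/stage, noise SD 0.5. Fixture bundles couple the two
species through an identity-plus-offset homology table (mapping logic,
not biology, is under test) and optionally bias KO-culture-up genes
toward the early archetype (probability 0.7), planting the cross-species
developmental signal the projection measures.

What the simulations do not emulate: probe-level hybridization effects,
multi-probe genes by default (a probe-expansion path exists in the
annotation fixtures only), glial admixture, correlated gene–gene noise,
non-Gaussian heavy tails, and uneven real-data stage coverage (936 NCX
vs 82 HIP samples). Passing recovery tests therefore establishes the
correctness of the estimators under the assumed model, not performance
on real arrays; the published-count checks establish the arithmetic of
the projection statistics exactly.

## Problem sizes and determinism

Default simulations use 2,000 genes (42 mouse samples; 90 human samples
per region) — large enough for stable hyperparameter estimation and
cluster recovery while keeping every run in seconds. Calibration checks
use 200 null replicates of 2,000 genes (type-I error) and 1,000 draws
(interval coverage). All randomness flows through explicit integer
seeds (numpy Generator); reruns are byte-identical, and k-means
determinism is guaranteed by seeding its restarts.

## Known limitations

- The moderated-t calibration is exact only under the hierarchical
  Gaussian model; heavy-tailed noise inflates the type-I error as it
  would for any t-based method (no robust variance option).
- The early/mid/late labeling assumes unimodal median profiles; strongly
  bimodal trajectories could be mislabeled by argmax.
- The common-universe construction assumes a many-to-one human→mouse
  homology map; paralog fan-outs must be resolved upstream.
- `PipelineConfig` validates YAML keys and dataset sources but not every
  nested simulation parameter; invalid values surface as the generator's
  own parameter errors.
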