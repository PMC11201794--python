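# Methods

## Model and procedure

The package treats a collection of K independent two-arm expression
studies ("cohorts") of the same biological contrast — control vs.
plasma-treated cancer cells — measured on heterogeneous microarray
platforms. Two parallel analyses are provided.

**Single-cohort re-analysis.** Each cohort is processed identically:
linear-scale intensities are detected by a max-value heuristic
(maximum > 50 ⇒ raw) and transformed as log2(x + offset), offset 1 by
default; columns are quantile normalized to the across-column mean of
order statistics; probes are collapsed to gene symbols by the arithmetic
mean on log2 scale. Differential expression uses a two-sample t with
empirical-Bayes variance moderation: gene-wise pooled variances s² (df =
n_t + n_c − 2) are shrunk toward a scaled inverse-chi-squared prior,
s̃² = (d₀s₀² + df·s²)/(d₀ + df), with (d₀, s₀²) fitted by method of
moments on log s² (the digamma/trigamma moment equations, trigamma
inverted by Newton iteration); the statistic is referred to a t
distribution with df + d₀ degrees of freedom. DEG calls use adjusted
p ≤ 0.05 ∧ |log2FC| ≥ 1, falling back to raw p ≤ 0.05 when no gene
passes, and to |log2FC| ≥ 1 alone when an arm has a single sample (no
test possible). Shared-DEG counting matches genes case-insensitively
across cohorts and preserves mixed directions.

**Meta-analysis.** Per gene and cohort, Hedges' adjusted g with the
large-sample variance (n_t+n_c)/(n_t·n_c) + g²/(2(n_t+n_c)); alternative
small-sample variance variants exist, this form is pinned. Pooling is
DerSimonian–Laird: Cochran's Q from fixed inverse-variance weights, the
moment estimator τ̂² truncated at 0, random-effects weights
1/(Var(gᵢ)+τ̂²). Directional evidence combines one-sided p-values from
the normal approximation z = g/√Var(g) (the per-cohort one-sided
construction is not uniquely standard; this choice is documented so
results are reproducible) via Fisher's sum of logs against χ²(2k), with
BH applied separately within the up and down families across genes.
Signature selection takes |pooled ES| ≥ 1, directional Fisher FDR ≤ 0.05
(inclusive at the boundary) and measurement in ≥ 5 cohorts, read as a
measurement requirement on the gene, with the thresholds applied to the
pooled quantities. Genes present in a single cohort are passed through
with τ² = 0 and flagged, never silently pooled. Validation scoring on a
cohort is the per-sample mean of the signature genes' log2 values, i.e.
the log2 geometric mean on linear scale.

**Enrichment.** Hypergeometric upper tail P(X ≥ overlap) — the inclusive
tail — over a universe defined as all genes measured after collapsing
(not the whole genome; genome-wide universes inflate significance), with
pathway members intersected with the universe before testing and BH
across tested pathways. The pathway hierarchy is a local child→parent
edge table; enriched pathways are mapped to every reachable root (a
pathway under multiple roots counts once per root), with a reserved
"unclassified" root for pathways absent from the hierarchy.

## Synthetic data: what it emulates, and what it does not

The generator draws per-gene baselines Normal(7, 1.5²) on log2 scale and
per-gene noise variances from a scaled inverse-chi-squared spread
(d = 10, s₀² = 0.25, i.e. typical SD 0.5), so variance moderation is
non-trivial; a planted subset of genes shifts the treated arm by
δ_{g,k}·σ_g with δ_{g,k} ~ Normal(δ, τ²) per cohort, up-regulated by
default (a flag plants mixed directions to exercise the down branch).
Each gene is emitted as several probe rows with Normal(0, 0.1²) probe
noise — collapsing matters but does not dominate — under one global
probe map, with optional per-cohort probe dropout to exercise
missing-gene handling. Defaults are the study conditions used throughout
the tests: 5 cohorts of 4+4 samples, 1000 genes, 50 plants at δ = 2,
τ² = 0, 3 probes per gene.

Not emulated: raw probe-level intensities and platform-specific
background correction, batch effects, correlated gene modules, and
asymmetric outlier samples. Passing tests therefore demonstrate the
statistical machinery under an idealized Gaussian log-intensity model,
not robustness to platform artifacts. The per-gene variance spread is a
modeling choice, not an estimate from real cohorts.

## Numerical choices and degenerate inputs

- Quantile-normalization ties receive the mean of the reference values
  over their tied ranks ("average ties" dialect; dialects differ). With
  ties present, columns' sorted vectors can differ from the reference by
  the tie-block averages; for continuous data all columns share the
  reference exactly. Single-sample matrices are returned unchanged with
  a warning.
- Zero-variance genes: in DE, t is undefined and p is set to 1 (the fold
  change is still reported) unless shrinkage provides a positive
  denominator; in effect-size computation the gene is excluded from the
  meta-analysis with a warning count.
- Per-cohort one-sided p-values are floored at 1e-300 before logs
  (configurable); zero p-values passed to the scalar Fisher combiner are
  clamped with a warning.
- PCA is computed on centered, unscaled log2 values over all genes, with
  samples as observations; components are bounded by min(samples−1,
  features).
- BH adjustment delegates to statsmodels' step-up implementation behind
  `bh_adjust`; PCA delegates to scikit-learn. Both are cross-checked in
  the test suite against brute-force/SVD oracles.
- TSVs everywhere (UTF-8, '.' decimal); gene symbols are matched
  case-insensitively across cohorts (platforms disagree on casing) with
  first-seen casing reported.

## Calibration behavior worth knowing

All quantities below are measured by `scripts/acceptance.py` and the
test suite at the default study conditions (5 cohorts × 4+4 samples).

- **Pooled-effect attenuation.** Because Var(g) contains g², cohorts
  with larger realized effects get smaller inverse-variance weights, so
  the DL pooled estimate of a planted δ = 2 averages ≈ 1.83 at 4+4
  samples per arm even though the raw Hedges' g is unbiased (mean
  ≈ 2.00). This is a property of the estimator at small n, shrinking as
  arms grow; CI coverage stays near nominal (≈ 93–96%) because τ̂²
  absorbs part of the weight distortion.
- **Fisher-p uniformity.** The one-sided normal approximation is exact
  only asymptotically; at 4+4 samples the combined Fisher p deviates
  from uniform by a KS distance of ≈ 0.04 (measured on p-values pooled
  over 20 independent null studies of 2000 genes). The χ²(k−1) reference
  for Q is likewise approximate at 4+4 (KS ≈ 0.06) and accurate by
  10+10 (KS ≈ 0.04). Neither deviation produces false signatures: under
  the global null, signature selection at FDR ≤ 0.05 returns an empty
  set in ≥ 95% of runs.
- **τ² recovery.** The DL moment estimator averages within a few percent
  of a planted τ² = 0.5 over hundreds of genes at k = 5, with large
  per-gene spread (k−1 = 4 degrees of freedom for heterogeneity).

## Problem sizes

Simulation-based checks use 5-cohort studies of 1000–2000 genes with
4+4 samples per arm, 3–20 replicate seeds per property, and one probe
per gene where probe redundancy is not the property under test; these
sizes give stable Monte-Carlo estimates (SEs of a few percent) while
keeping the full suite under a few seconds.

## Known limitations

- Pooled-variance (not Welch) t throughout, consistent with the
  moderated framework; unequal-variance arms are not modeled.
- No multi-factor or paired designs, array weights, or batch correction.
- DL is the only τ² estimator (no REML), and no leave-one-out or
  publication-bias diagnostics are provided.
- Rank-based (GSEA-style) enrichment and topology-aware pathway scoring
  are out of scope; enrichment is membership-only ORA.
- The relaxed DEG fallback triggers on zero stringent DEGs cohort-wide;
  at 4+4 samples with BH over 1000 genes this is common, which mirrors
  the intended use of the fallback for under-powered cohorts.
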