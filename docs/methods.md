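# Methods

## Scope and model

The package operates entirely at the summary-statistic level. Its units are
per-SNP association records (effect β on an inverse-normal-transformed
trait, standard error, effect-allele frequency, p, n), and all inference
composes four stages: fixed-effect pooling, locus calling, single-variant
Bayesian fine-mapping, and two-sample Mendelian randomization (MR).

### Fixed-effect meta-analysis and genomic control

Per SNP, cohorts are pooled with weights wᵢ = 1/seᵢ² (β̂ = Σwβ/Σw,
se = (Σw)^(−1/2)); this is the generalized-least-squares solution of an
intercept-only weighted regression, which the test suite uses as an
independent oracle. SNPs carried by only some cohorts are pooled over the
cohorts that have them, with K (number of contributing studies) stored per
SNP — K feeds the fine-mapping Bayes factor later. Two-sided p-values come
from the normal distribution (equivalent to the 1-df chi-square; chosen for
determinism of the code path).

Genomic control estimates inflation as λ = median(z²)/0.4549364 (the median
of χ²₁). Only inflation is corrected: when λ > 1 every z is divided by √λ
and standard errors multiplied by √λ; deflation is recorded but never
applied, the standard convention. The default applies one correction to the
meta-analyzed statistics; a per-cohort pre-correction mode is provided for
pipelines that prefer it, since published workflows are ambiguous about the
order.

### Loci and novelty

A locus is a ±250 kb window anchored on a lead SNP. Among
genome-wide-significant SNPs (p < 5×10⁻⁹, strict), leads are assigned
greedily in p-ascending order, with ties broken by (chromosome, position)
so that output is invariant to input row order. Distance exactly equal to
the window counts as inside. Novelty is judged on the lead SNP against a
user-supplied reference list of (chromosome, position) points — the lead is
"known" within ±250 kb of any reference point. Cross-trait de-duplication
of loci is offered as an optional union (re-clustering pooled leads) but no
composite locus count is asserted anywhere, because de-duplication
conventions vary.

### Fine-mapping

Under a single-causal-variant assumption the per-SNP Bayes factor is

    BFᵢ = exp[(Zᵢ² − ln Kᵢ)/2]

with Kᵢ the per-SNP study count. This deliberately simple form — it omits
the prior-variance shrinkage term of Wakefield-style approximate Bayes
factors — makes the posterior a function of z² and K only. `ln` is the
natural logarithm; a `log_base` parameter exists as a guard for the base-10
reading. Posterior probabilities PPᵢ = BFᵢ/ΣBFⱼ are computed in log space
(max-z² centring), so loci with |z| of 40 and beyond normalize without
overflow even though the raw BF exceeds float64 range past |z| ≈ 38. The
99% credible set is the smallest PP-descending prefix with cumulative
PP ≥ 0.99 (comparison carries 1e−12 slack for float error; minimality is an
asserted invariant). Ties in PP break by |z| descending then SNP id. A top
SNP with PP strictly above 0.5 flags the signal high-confidence. The
fine-mapped region is the lead ±250 kb including non-significant SNPs.

### Mendelian randomization

Instruments: genome-wide-significant exposure SNPs, greedily clumped so
that accepted SNPs are pairwise r² < 0.001 or more than 250 kb apart; SNPs
missing from the LD matrix are treated as unlinked with a logged warning.
Instruments absent from the outcome can be replaced by user-supplied
proxies (best proxy with r² ≥ 0.8 present in the outcome), mirroring
LD-proxy lookups without any web dependency. Outcome effects are aligned to
the exposure's effect allele with the same swap/flip rules used for cohort
harmonization.

Estimators (J instruments, ratios Rⱼ = βᵧⱼ/βₓⱼ, weights wⱼ = (βₓⱼ/seᵧⱼ)²):

* **IVW** (fixed-effect, first-order weights): θ̂ = Σwⱼ Rⱼ/Σwⱼ in
  through-origin-WLS form; J = 1 degenerates to the Wald ratio with a
  warning. Multiplicative random-effects scaling is not applied by default.
* **MR-Egger**: WLS of βᵧ on βₓ with intercept (weights 1/seᵧ²), after
  orienting βₓ ≥ 0; the slope estimates the causal effect under InSIDE, the
  intercept tests directional pleiotropy. The fit itself is delegated to
  statsmodels WLS.
* **Weighted median**: ratios ordered ascending, standardized cumulative
  weight sⱼ = (cumⱼ − wⱼ/2)/Σw, linear interpolation at s = 0.5; the se is
  a parametric bootstrap (redraw βₓ, βᵧ from normals at their se's; seeded,
  count configurable).
* **Cochran's Q** around any estimate, df = J − 1, upper-tail χ² p.
* **Pleiotropy exclusion**: one pass over per-SNP Q contributions against
  the χ²₁ upper quantile at Bonferroni level α/J, then one re-estimate —
  a single pass avoids iterative outlier-chasing.

`implied_wald_p` back-computes the two-sided p from an estimate and its 95%
CI (se = width/(2·1.959964)), the consistency check applied to published
IVW results.

## Synthetic data: what it emulates, and what it does not

The generator works at the summary level because the pipeline consumes only
summaries; no genotypes or phenotypes are simulated.

* Per locus, z-scores are multivariate normal with AR(1) correlation
  R = ρ^|i−j| (default ρ = 0.5) — a deliberate simplification of real
  haplotype LD. A causal SNP contributes mean (R e_c)·causal_z, split
  across cohorts as √(n_k/n_total) so the meta-analysis recovers the full
  non-centrality. Betas are back-computed via se = 1/√(2nf(1−f)), so all
  records pass the Wald-consistency validator.
* Defaults mirror the motivating study's scale: two cohorts of 2,741 and
  15,061 samples; 20 loci × 50 SNPs at 10 kb spacing with 1 Mb gaps;
  allele frequencies uniform on [0.05, 0.5]; causal z = 8.
* MR sets: βₓ ~ |N(0, 0.05²)| truncated below at 0.01 (positive
  orientation = exposure-increasing allele; the truncation keeps Wald
  ratios stable), se from an exposure of n = 17,802 and an outcome of
  n = 14,654; βᵧ = θβₓ + α + ε with α = 0 for valid instruments and
  α ~ N(0.02, 0.01²) for the pleiotropic fraction, drawn independently of
  βₓ (InSIDE holds by construction). The drawn βₓ is also the observed βₓ
  (no extra measurement noise), so the exposure association is treated as
  exactly estimated; θ̂ recovery is then limited by outcome noise only.

Passing tests on this generator demonstrate estimator correctness and
calibration under idealized LD, Gaussian noise and exact se's. They do not
demonstrate robustness to real-data features the generator omits: strand
mixups beyond palindromes, population stratification, overlapping samples
between exposure and outcome, allele-frequency mismatch between studies, or
winner's-curse bias in instrument selection.

## Numerical choices

* z/p consistency tolerance on input records: |2Φ(−|z|) − p| ≤ 0.05
  (an integrity screen, not a statistical test).
* Palindromic (A/T, C/G) SNPs dropped when MAF > 0.4, configurable.
* MAF filter strictly greater-than (boundary excluded).
* p-values floored at the smallest positive double to keep them in (0, 1].
* Credible-set cumulative comparison carries 1e−12 slack; PP normalization
  is exact to 1e−9 by construction.
* All simulation randomness flows from one integer seed through
  `numpy.random.default_rng`; identical configs are bit-identical.

## Known limitations

* Single-causal-variant fine-mapping only; no conditional or multi-signal
  analysis, no functional priors.
* The weighted median is consistent only while per-ratio noise is small
  relative to the estimand. With weak instruments (βₓ near the truncation
  floor) the ratio noise sd seᵧ/βₓ can exceed θ itself, and a directional
  30%-invalid mixture then shifts the weighted 50% point noticeably upward
  — the recovery experiments in `scripts/acceptance.py` quantify this
  (weighted-median mean ≈ 0.26 for θ = 0.2 under the default pleiotropy
  scenario, versus ≈ 0.20 for MR-Egger, whose consistency needs only
  InSIDE, not low ratio noise). Practitioners should read the weighted
  median alongside Egger, not as a drop-in robust replacement for IVW.
* Genomic-control λ is a blunt inflation correction; no LD-score-style
  decomposition of polygenicity vs confounding is attempted.
* Positions are opaque 1-based coordinates; no genome-build handling or
  liftover.
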