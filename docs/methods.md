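# Methods

## Model

Two-sample MR treats genetic variants as instruments for an exposure. For
variant $j$, the exposure GWAS reports $\hat\gamma_j \sim N(\gamma_j,
\sigma_{Xj}^2)$ and the outcome GWAS reports $\hat\Gamma_j \sim N(\Gamma_j,
\sigma_{Yj}^2)$, with the structural relation

$$\Gamma_j = \beta\,\gamma_j + \alpha_j,$$

where $\beta$ is the causal effect of a 1-SD increase in the exposure on the
outcome (log odds for a binary outcome) and $\alpha_j$ is the variant's
direct (pleiotropic) effect. The three instrument assumptions are: (1)
relevance ($\gamma_j \neq 0$, checked by the significance filter and
F-statistics), (2) independence from confounders (not checkable from summary
data), and (3) exclusion restriction ($\alpha_j = 0$; its violation is what
the Egger intercept, the median estimators, and leave-one-out probe).

Estimators, for harmonized pairs $(\hat\gamma_j, \hat\Gamma_j)$ with weights
$w_j = 1/\sigma_{Yj}^2$:

- **IVW**: weighted through-origin regression slope. Fixed-effect SE is
  $1/\sqrt{\sum w_j \hat\gamma_j^2}$; the default multiplicative
  random-effects model multiplies it by $\max(1, \sqrt{Q/(k-1)})$, where
  $Q$ is the weighted residual sum of squares. The heterogeneity statistic
  $Q$ is used only for this inflation, never reported as a test. The
  fixed/random choice is exposed because published ORs rarely state which
  was used; both give the same point estimate.
- **MR-Egger**: weighted regression with intercept after recoding so all
  $\hat\gamma_j \ge 0$. SEs are inflated by $\max(1, \sqrt{RSS_w/(k-2)})$
  and inference uses $t(k-2)$. The inflation floor makes the intercept test
  slightly conservative when the data are under-dispersed (measured type-I
  error ≈ 4–5% at nominal 5% with $k = 100$), which we accept in exchange
  for never reporting an SE below the weighted-fit baseline.
- **Medians**: per-variant ratios $r_j = \hat\Gamma_j/\hat\gamma_j$ sorted;
  with normalized weights the estimate interpolates the weighted quantile at
  0.5 using midpoint cumulative weights $p_j = \sum_{i\le j} w_i - w_j/2$.
  Weighted weights are $\hat\gamma_j^2/\sigma_{Yj}^2$ (the first-order
  inverse variance of $r_j$). The SE is a parametric bootstrap: redraw
  $\hat\gamma_j, \hat\Gamma_j$ from their sampling distributions centred on
  the observed values, recompute, take the SD over `n_boot` draws (default
  1000; seed mandatory). Because the bootstrap convolves the sampling noise
  with data that already contain it, the SE is mildly conservative: measured
  95% CI coverage is ~97–98% where IVW and Egger sit at ~95%.
- **Wald ratio** ($k=1$): $\hat\Gamma/\hat\gamma$ with first-order SE
  $\sigma_Y/|\hat\gamma|$ (the IVW $k=1$ reduction) or the second-order
  delta-method SE including exposure noise.

## Harmonization

Matching is by variant id only (rsID-level GWAS tables). Outcome records
whose alleles are swapped relative to the exposure — directly or on the
complementary strand — have their beta negated and EAF flipped. Palindromic
pairs (A/T, C/G) cannot be resolved by letters; by default
(`infer_by_eaf`) they are oriented by comparing effect-allele frequencies,
dropped when either frequency lies within 0.5 ± 0.08 or is missing. The band
and a hard `drop` policy are configurable, since published analyses often
leave this choice unstated. Harmonization is idempotent and invariant to
re-coding the outcome file's alleles.

Proxy substitution (for instruments absent from the outcome study) picks the
outcome-present variant with the highest LD $r^2$ strictly above the
threshold (default 0.9), ties broken by smaller exposure p then variant id.
In the pipeline the proxy's own exposure and outcome records are harmonized
and recorded under the target id; if the proxy has no exposure record, the
target's exposure stats are paired with the proxy's outcome stats as
reported, which assumes the proxy's effect allele tags the target's — users
with real panels should supply the proxy's exposure row.

## Instrument diagnostics

The set-level F-statistic uses the multi-instrument regression form
$F = \frac{r^2}{1-r^2}\cdot\frac{n-k-1}{k}$; the per-variant screen is the
squared Wald statistic $(\hat\gamma/\sigma_X)^2$ with the conventional
$F > 10$ rule. Power for a binary outcome uses the normal-approximation
non-centrality $\lambda = |\ln OR|\sqrt{n\,r^2\,cf(1-cf)}$, power
$= \Phi(\lambda - z^*) + \Phi(-\lambda - z^*)$; it equals $\alpha$ exactly
at $OR = 1$ and matches simulated IVW power within Monte-Carlo error (the
approximation ignores exposure-side noise, negligible when per-variant
F ≫ 10).

## Synthetic data

The generator simulates summary statistics directly — no individual-level
genotypes — because the analysis consumes nothing else and this keeps every
test desk-scale. Per variant: MAF uniform on `maf_range` (default
0.05–0.5); $\gamma_j$ positive (the effect allele is taken as the
exposure-increasing allele, the usual instrument-table convention, which is
also what makes directional pleiotropy a recoverable quantity), magnitudes
$0.3 + |N(0,1)|$ so no instrument is degenerate, rescaled so
$\sum_j 2p_j(1-p_j)\gamma_j^2$ hits the target variance explained exactly;
$\alpha_j$ zero, $N(0, sd^2)$ (balanced) or $N(mean, sd^2)$ (directional)
on a configurable fraction of variants; standard errors
$1/\sqrt{2np(1-p)}$, divided by $\sqrt{cf(1-cf)}$ when a binary-outcome
case fraction is set. A configurable fraction of variants is palindromic and
a fraction of outcome rows is re-encoded with swapped alleles and negated
betas to exercise harmonization. LD is block-diagonal with constant
within-block $r^2$.

What it does **not** emulate: winner's curse in instrument discovery, sample
overlap between studies, LD-correlated effect sizes, ancestry-specific
frequency structure, or non-normal effect-size distributions. Passing tests
therefore demonstrate correctness of the estimators and pipeline under the
model's own assumptions, not robustness to those real-data complications.

Default study conditions used by the test suite and acceptance script:
exposure n = 300,000, outcome n = 50,000, variance explained 10% over
k = 50–100 instruments (per-variant F ≈ 300, so weak-instrument attenuation
is negligible next to the estimators' SEs); calibration runs use 200–2000
replicates, chosen so Monte-Carlo error is comfortably inside each
acceptance band.

## Numerical choices

- p-values are clipped to the smallest positive double rather than reported
  as 0; full precision is kept everywhere, scientific formatting
  (3 significant digits, `m x 10^k` below 10⁻³) only in the text report.
- Greedy LD pruning ranks by (p, variant id) so ties are deterministic;
  absent LD pairs count as $r^2 = 0$ unless strict mode is requested.
- Degenerate inputs raise typed errors (`InsufficientInstrumentsError`,
  `DegenerateDesignError`, `DomainError`) instead of returning NaNs;
  leave-one-out at $k-1 = 1$ falls back to the fixed-effect model.
- The bootstrap guards against zero resampled $\hat\gamma_j$ (infinite
  ratios are possible but measure-zero; weights $\hat\gamma^2/\sigma_Y^2$
  suppress them in the weighted median).
- Binary exposures (e.g. disease liabilities) should use scale factor 1
  (effects already per log-odds); "per 10 units" reporting for continuous
  traits is a per-exposure configuration, not a global default.

## Known limitations

One-sample MR, multivariable MR, mode-based estimators, MR-PRESSO, Steiger
filtering, and nonlinear exposure-outcome models are out of scope. LD
$r^2$ is an input, never computed from genotype panels. Reproducing
published ORs for real exposures requires the corresponding external GWAS
summary files; the package ships none.
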