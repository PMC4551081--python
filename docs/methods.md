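# Methods

## Model family and estimation

All members of the family — uSEM, euSEM, GIMME — are structural VARs
fitted *directly* (not via a standard VAR plus Cholesky rotation, which
would make the contemporaneous paths depend on variable ordering). The
data enter as a block-Toeplitz second-moment matrix: variables are
ordered [y(t), y(t−1), …, y(t−a), inputs, products], the lag-l blocks
are estimated as C(l) = (1/(T−l)) Σ_t y(t) y(t−l)ᵀ and tiled, so blocks
on the same diagonal offset are *identical by construction*. For input
models the HRF-convolved condition vector at lags 0..f and the centered
bilinear products y_j(t−q)·u(t−r) are appended as extra exogenous
columns, with their covariances computed over the aligned rows.

The first p variables (current time) are endogenous; everything else is
exogenous with a saturated (free) covariance Σ_xx. The Gaussian ML
discrepancy F_ML is minimised over the freed regressions (A, Φ_q, γ_r,
τ_{q,r}) and the p innovation variances Ψ. Because the likelihood
factors into an exogenous marginal and an endogenous conditional, the ML
solution for Σ_xx is exactly the sample block S_xx; we profile it out of
the optimisation but keep its elements as free parameters in the df
bookkeeping and in the expected (Fisher) information. Consequences:

- df = m(m+1)/2 − (m−p)(m−p+1)/2 − p − k_free, which reproduces the
  published 7 / 17 / 15 for the three-ROI models.
- Standard errors come from (2/(n_eff−1)) H⁻¹ with
  H_jk = tr[Σ⁻¹ ∂Σ_j Σ⁻¹ ∂Σ_k]; 95% CIs are estimate ± 1.96 SE. A
  coverage Monte Carlo (confirmatory true-structure fit, 100 replicates
  of the three-ROI scenario) measures 0.95–0.98 per parameter.
- Modification indices are score tests:
  MI = (n_eff−1)/2 · g², divided by the candidate's information
  conditioned on all free parameters. Against a free-and-refit oracle on
  small models the relative error is below 25% and the significance
  decision at 3.84 agrees in ≥ 99% of candidates.

Numerics: quasi-Newton (L-BFGS-B) on F_ML with the analytic gradient
2(ΣGM)ᵀ for regressions and diag(MᵀGM) for variances
(G = Σ⁻¹ − Σ⁻¹SΣ⁻¹, M = (I−Ã)⁻¹); start values are zero regressions and
sample variances; innovation variances are bounded below at 1e−10 with a
Heywood warning at 1e−8; convergence is declared at gradient norm 1e−6;
chi² = (n_eff−1)·F with n_eff = T − a for connectivity fits and
(T−a) − 3 for white-noise fits (the number of usable embedded rows — the
convention is recorded in every FitResult). A singular lagged covariance
produces a warning, not an error.

## Search

The data-driven search starts from the null model, computes MIs for all
candidate paths (off-diagonal A, all Φ_q, plus γ/τ for input models) and
frees the largest significant one (χ²(1), α = .05, uncorrected; ties
broken lexicographically by lag/target/source). It stops when the 2-of-4
excellent-fit rule passes *and* no remaining MI survives a Bonferroni
correction over the candidate set, or when no MI is significant at all;
freed parameters are then Wald-trimmed (p ≥ .05 removed iteratively,
innovation variances and exogenous covariances never pruned). The
two-tier stop matters at long T, where CFI/SRMR are nearly always
excellent yet a strongly significant path (e.g. a direct task effect)
remains; the Bonferroni tier keeps the search from quitting early while
leaving pure-noise data untouched (on white-noise data ≤ 1 path is freed
in ≥ 95% of replicates).

The direction of a contemporaneous path is nearly invisible to its MI
(the statistic is dominated by the symmetric lag-0 covariance) and is
identified only through the lagged structure. Two safeguards address
this: when an A candidate wins, both orientations are refitted and the
better chi² kept; and after trimming, every freed A path is re-checked
against its reverse under the final lagged structure (orientation
sweep), iterating free/trim/sweep up to three rounds. Reciprocal pairs
that make I−A singular are reverted and skipped.

GIMME stage 1 grows the group structure: a candidate is freed for all
subjects when its MI is significant for at least ceil(criterion·n)
subjects (criterion default 0.75; ties by summed MI), stopping when that
many subjects fit excellently; group paths Wald-significant for too few
subjects are dropped. The group orientation sweep additionally tries
each reversed path together with the new source's lag-1 autoregression —
a reversed "sink" configuration is self-consistent precisely when that
autoregression is missing — comparing alternatives of different size by
an AIC-style chi² + 2nk score. Stage 2 runs the individual search per
subject with the group structure as its protected base, so group
connections stay estimated (with subject-specific magnitudes and signs)
while individual connections are freed and trimmed.

## White-noise validation

Prediction errors ζ̂(t) are computed in the time domain from the fitted
coefficient matrices, dropping the first max(a, input-lag) points. The
white-noise test builds the residuals' block-Toeplitz covariance at
L = 3 and fits the null model Σ = I_{L+1} ⊗ C with one free p×p
contemporaneous covariance C — all lagged blocks fixed at zero. Its ML
solution is closed-form (C equals the lag-0 block), giving
chi² = (n−1)[(L+1)·ln det C(0) − ln det S] and
df = m(m+1)/2 − p(p+1)/2 (72 / 126 / 378 for p = 3 / 4 / 7). The test
passes when the null model meets the same 2-of-4 rule used for model
acceptance; the MI table reports the score statistic of every lagged
residual regression (target, source, lag 1..L).

Decision policy on failure: at most `few_threshold` (default 5)
significant residual MIs are treated as an interpretable pattern and
freed confirmatorily (option a); the mapping is (target, source, lag) →
Φ_lag[target, source], a dependency landing on an already-free parameter
escalates one lag at the same indices (the modelled lag is too shallow
there), and mapped lags reach at most one above the current order.
Confirmatory refits end with the family's usual Wald trimming. Anything
else triggers a fresh data-driven search one order higher (option b)
with the permanent base — the GIMME group structure for multi-subject
data — always retained. Option c (subdividing a long, possibly
non-stationary series) is never chosen automatically. The loop accepts
when the test passes, and gives up when the order would exceed
`max_order` (default 3) or a previously-visited specification recurs
(guaranteeing termination).

## Synthetic data

The generator iterates y(t) = (I−A)⁻¹(Σ_q Φ_q y(t−q) + input terms +
ζ(t)) with Gaussian innovations (identity covariance by default),
refuses non-stationary specifications (companion spectral radius ≥ 1),
and discards a 500-sample burn-in — safely past mixing for spectral
radii ≤ 0.9. Long-run moments match the companion-form Lyapunov solution
within 2% at T = 50 000. Randomness is pinned to numpy's default
Generator with an explicit seed, so output is bit-reproducible.

The canonical single-subject scenario has 3 ROIs, T = 200, order 2 and
six nonzero coefficients: lag-1 autoregressions on all ROIs (0.4), an
extra lag-2 autoregression on ROI 3 (0.3), a contemporaneous path
ROI3 → ROI1 (0.5) and a cross-lag ROI1 → ROI2 (0.4). The magnitudes are
package defaults, chosen to be comfortably stationary and individually
detectable at T = 200; they are overridable and not presented as
empirical values. The multi-subject generator emulates a resting-state
design: 32 subjects, 4 ROIs, T = 160, a shared group structure (per-ROI
lag-1 autoregression plus four contemporaneous paths) jittered ±0.1
uniformly per subject, two subject-specific extra connections (|β| ≈
0.3) from a fixed pool, and one lag-2 autoregression (β = 0.4) for a
designated fraction of subjects (default one half). What it deliberately
omits: HRF variability across regions, physiological noise, drift and
motion artefacts, and non-Gaussian innovations — so passing tests speak
to the statistical machinery under the model's own assumptions, not to
robustness against real-data nuisance structure.

## Sensitivity limits and known limitations

The white-noise test inherits the family's 2-of-4 index rule, and
on a block-Toeplitz covariance the null chi² is stochastically *smaller*
than its printed df (the tiled moments are not independent; for p = 3,
L = 3 the null mean is ≈ 54 against df 72, sd ≈ 16). RMSEA therefore
almost never rejects, and the operative indices are CFI/NNFI, whose
baseline on nearly-white residuals is itself small — making both the
specificity and the power of the test intrinsically moderate at
T ≈ 200. Measured behaviour: i.i.d. 3-variate residuals pass in ~85% of
replicates; a single AR(1) residual series with coefficient 0.5 fails in
100%; the order-1 map of the canonical second-order scenario (lag-2
coefficient 0.3) fails in ~60–72% — essentially the ceiling for this
effect size, since a standard VAR(3) likelihood-ratio test on the same
residuals rejects only ~53%. Consequently, at these small simulated
effect sizes the full pipeline recovers the second order in ~60% of
replicates rather than nearly always; with larger generating
coefficients the test saturates quickly. Other known limitations: a
contemporaneous "sink" configuration (several reversed paths into one
node whose autoregression is absent) can survive the orientation sweeps
on occasional group replicates; euSEM supports a single input vector;
and missing data are not supported — series must be complete.

## Problem sizes used in the shipped checks

Monte-Carlo checks run at the scenario sizes above: 100 replicates for
the single-subject pipeline and CI coverage, 200 for white-noise
calibration and power, 50 random models for the MI oracle, and 20
replicates × 12 subjects per condition for the group pipeline — sizes
chosen so the whole battery completes in a couple of minutes while
keeping Monte-Carlo error a few percentage points.
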