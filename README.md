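# usem — directed functional connectivity with temporal-order validation

`usem` maps **directed functional connectivity** among brain-region (ROI)
time series with the unified-SEM family of structural vector
autoregressions, and then — the part most pipelines skip — **validates
the temporal order of the map a posteriori** by white-noise testing of
its one-step-ahead prediction errors, revising the map to higher lag
orders until the residuals carry no sequential dependence.

It is written for researchers analysing fMRI ROI time series (task or
resting state) who want contemporaneous *and* lagged directed
connections in one model, at the single-subject and the group level,
with an explicit check that the modelled lag order was enough.

## The models

A uSEM of order *a* for a centered p-variate series η(t) is

    η(t) = A η(t) + Φ₁ η(t−1) + … + Φ_a η(t−a) + ζ(t)

with contemporaneous matrix **A** (diagonal fixed at zero), lagged
matrices **Φ_q**, and serially independent innovations ζ with diagonal
covariance Ψ. The extended model (euSEM) adds direct effects **γ_r** of
an HRF-convolved task input u(t−r) and bilinear modulations
**τ_{q,r}** η(t−q)u(t−r). GIMME fits uSEMs to many subjects at once,
splitting every matrix into a group part shared by the sample and an
individual part per subject.

All models are estimated as Gaussian covariance-structure models on the
**block-Toeplitz** arrangement of the lag-0..a cross-covariance blocks,
by minimising F_ML = ln det Σ(θ) + tr(S Σ(θ)⁻¹) − ln det S − m.
Structure is found in a data-driven way by sequential Lagrange-multiplier
(modification-index) freeing and Wald trimming; model acceptance uses the
2-of-4 rule RMSEA ≤ .05, SRMR ≤ .05, CFI ≥ .95, NNFI ≥ .95.

Validation computes the realized innovations
ζ̂(t) = η(t) − Âη(t) − ΣΦ̂_q η(t−q) − (input terms), lays a lag-3 VAR on
their block-Toeplitz covariance, and fits the null model that fixes
every lagged coefficient at zero (one repeated free contemporaneous
covariance; df = m(m+1)/2 − p(p+1)/2, e.g. 72 for p = 3). If that null
fails the 2-of-4 rule, residual modification indices decide whether a
few parameters are freed confirmatorily (option a), a data-driven search
is rerun one order higher (option b), or — only on explicit request —
the series is subdivided (option c). The loop repeats until the
residuals are white or the order budget (default 3) is exhausted.

## Worked example

Simulate the canonical 3-ROI second-order scenario (six true
connections, identity innovations, T = 200), fit a first-order
data-driven uSEM, and validate:

```python
from usem import SearchConfig, usem_search, validate, center
from usem.synthesis import second_order_scenario, simulate_usem

ts = center(simulate_usem(second_order_scenario(seed=1)))
cfg = SearchConfig(order=1)
spec, params, fit = usem_search(ts, cfg)
trace = validate(ts, params, cfg, fit=fit)
print(trace.report())
```

```
== Iteration 1: order-1 model, 5 freed ==
MODEL FIT
  chi2(7) = 10.85 (p = 0.146), RMSEA = 0.05, SRMR = 0.04, CFI = 0.99, NNFI = 0.98
WHITE NOISE TEST
  chi2(72) = 88.27 (p = 0.093), RMSEA = 0.03, SRMR = 0.08, CFI = 0.44, NNFI = 0.48
white noise: FAILED; action: option_a
== Iteration 2: order-2 model, 7 freed ==
MODEL FIT
  chi2(14) = 16.06 (p = 0.310), RMSEA = 0.03, SRMR = 0.02, CFI = 1.00, NNFI = 0.99
WHITE NOISE TEST
  chi2(72) = 47.42 (p = 0.989), RMSEA = 0.00, SRMR = 0.06, CFI = 1.00, NNFI = -0.67
final order: 2 (accepted)
```

The first-order map fits well by the 2-of-4 rule yet its residuals are
not white (the white-noise null fails on CFI/NNFI), so the loop frees
the parameters indicated by the residual modification indices and
settles on a second-order map whose residuals pass. The accepted map
recovers the generating structure; for example the contemporaneous
path ROI3 → ROI1 (true value 0.50) is estimated as

```
('A', 0, 2): +0.494  95% CI [+0.350, +0.639]
('Phi', 2, 2, 2): +0.264  95% CI [+0.130, +0.399]   # the lag-2 term the order-1 map missed
```

The same workflow is available from the shell:

```bash
usem simulate --scenario second-order --out sim --seed 1
usem fit sim/subj1.tsv --model usem --order 1 --out fit
usem validate sim/subj1.tsv --model-json fit/model.json --out val
usem report --model-json fit/model.json --format graphml --out map.graphml
```

For multi-subject data, `usem fit --model gimme subj*.tsv` estimates the
group and individual structure, and `usem validate` reports the count
and fraction of subjects whose maps need lags above one.

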