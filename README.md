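# sizespectra

**Global body size–biomass spectra with propagated uncertainty.**

How is the biosphere's standing biomass distributed across the ~26
orders of magnitude of organism body size, from archaea (~10⁻¹⁷ g C)
to giant sequoias (~10⁹ g C)? This package reconstructs that
distribution from group-level summaries — for each of 36 free-living
biological groups (16 terrestrial, 18 marine, 2 subterranean): total
biomass `B` (Gt C), a 95% fold uncertainty `λ`, and minimum / median /
maximum body sizes (g C) — and characterizes the resulting spectra
statistically. It is aimed at macroecologists working with size
spectra and at anyone who needs a tested reference implementation of
the underlying pipeline.

## The model

Within a group, biomass over log₁₀ size `x` follows a generalized
extreme value (GEV) density `y(x) = B·f(x; μ, σ, ξ)` truncated to
`[log₁₀ min − 2, log₁₀ max]` and renormalized, where

    f(x) ∝ (1/σ) · t(x)^(ξ+1) · e^(−t(x)),
    t(x) = (1 + ξ·(x−μ)/σ)^(−1/ξ)   (ξ ≠ 0),  e^(−(x−μ)/σ)  (ξ = 0).

Parameters are set by quantile matching: the truncated distribution's
0.05th/50th/99.95th percentiles are fit to the reported min/median/max
(≈99.9% of biomass inside the reported range). Uncertainty propagates
by a two-step bootstrap: per replicate, the median size is resampled
from the initial fit and the biomass from a lognormal with
`sd(log₁₀B) = log₁₀λ/1.96`, then the distribution is refit. Cumulative
spectra (Gt C per log₁₀ size, 40 bins per decade over [−18, 11]) are
summed per habitat realm and summarized by power laws (exponent β; on
the abundance scale, α = β − 1), Gaussian mixtures (1–4 components,
R², AICc), and 95% bootstrap envelopes. See `docs/methods.md` for the
full account.

## Worked example

```python
from sizespectra import RunConfig, run_pipeline

result = run_pipeline(RunConfig(n_boot=1000, seed=1))
for row in result.table_rows():
    print(f"{row['realm']:12s} beta = {row['beta_mean']:.3f} ± {row['beta_sd']:.3f}"
          f"   alpha = {row['alpha_mean']:.3f} ± {row['alpha_sd']:.3f}")
for x, dens in result.realms["all"].median_modes[:2]:
    print(f"mode at 10^{x:.1f} g C: {dens:.0f} Gt per log10 size")
```

prints (three to four minutes on one core):

```
all          beta = 0.079 ± 0.013   alpha = -0.921 ± 0.013
terrestrial  beta = 0.093 ± 0.019   alpha = -0.907 ± 0.019
marine       beta = 0.026 ± 0.016   alpha = -0.974 ± 0.016
mode at 10^9.1 g C: 104 Gt per log10 size
mode at 10^7.4 g C: 65 Gt per log10 size
```

Read: biomass is nearly flat across size classes (β close to 0
everywhere, and essentially zero in the ocean), so abundance falls
almost exactly as 1/mass (α ≈ −0.9). On top of that flat trend the
global spectrum is concentrated at the extremes — microbes near
10⁻¹⁵ g and large plants near 10⁷ g (the ~65 Gt per log size mode;
the denser value just below 10⁹·²  g sits where several plant groups'
upper size limits coincide with the model's upper truncation bound) —
while intermediate sizes carry on the order of 1 Gt per log size. A
two-component Gaussian mixture accordingly describes the spectrum far
better than the power law (mean R² 0.81 vs 0.40 across replicates).

The same analyses are scripted end to end under `analysis/`
(`01_size_ranges.py` … `06_synthetic_recovery.py`), writing their
tables to `results/`; `sizespectra run|variant|synth|range-stats`
exposes them on the command line.

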