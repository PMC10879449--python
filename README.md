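# dyadsync

Second-by-second parent–child physiological synchrony in respiratory sinus
arrhythmia (RSA), from raw heartbeat times to cohort-level summaries.

RSA — the respiration-linked oscillation in heart period, an index of vagal
(parasympathetic) cardiac influence — fluctuates from moment to moment during
social interaction, and parents' and children's fluctuations can be coupled.
`dyadsync` is for researchers studying such dyadic coupling: it estimates
each partner's time-varying RSA as log spectral band power over sliding 32-s
windows, then asks, separately for every dyad and interaction task, whether
one partner's RSA fluctuation at second *t−1* predicts the other's at second
*t* beyond that partner's own stability.

## The model

Per dyad-task, with `y_t = (parent_t, child_t)` in ln ms²:

```
y_t − μ = Φ (y_{t−1} − μ) + e_t,   e_t ~ N(0, Σ),   Φ = [ φ_p   β_c→p ]
                                                        [ β_p→c  φ_c  ]
```

The cross-lags are the synchrony parameters: `β_p→c` is parent-driven
synchrony, `β_c→p` child-driven. Estimation is Bayesian (blocked Gibbs
sampler, latent mean centring, inverse-Wishart innovation prior, missing
seconds by data augmentation) with two chains, Gelman–Rubin PSR < 1.05 early
stopping, and an admissibility safeguard that discards draws whose
standardized autoregressive coefficients exceed 1. A cross-lag is classified
positive / negative / null according to whether its 95% credible interval
lies above, below, or across zero. Cohort summaries report analyzable Ns,
per-category percentages, and cross-task Cohen's kappa per category.

Because real recordings of this kind are rarely shareable, the package ships
a first-class synthetic-data module: per-second RSA trajectories from a
stationary bivariate lag-1 process are encoded into beat times whose
respiratory-band modulation carries exactly the target band power
(`A(t) = sqrt(2 exp(rsa(t)))`), plus ectopic-beat and dropout corruption with
a ground-truth map. Every pipeline stage is validated against analytic or
simulation oracles. See `docs/methods.md` for the full model description,
defaults, and limitations.

## Worked example

Simulate one dyad with known child-driven coupling (`β_c→p = 0.3`,
`β_p→c = 0`), screen, fit, and classify:

```python
import numpy as np
from dyadsync import MCMCConfig, classify_synchrony, fit_dyad_var, screen_dyad
from dyadsync.validation import default_var_params, rsa_record_from_series
from dyadsync.synthetic import simulate_var_series

params = default_var_params(beta_parent_to_child=0.0, beta_child_to_parent=0.3)
rsa_p, rsa_c = simulate_var_series(params, 300, seed=1)
record = rsa_record_from_series(rsa_p, rsa_c, dyad_id="dyad001", task="conflict")

post = fit_dyad_var(record, MCMCConfig(seed=2, max_iterations=5000,
                                       min_iterations=1500, check_interval=250))
for name in ("beta_child_to_parent", "beta_parent_to_child"):
    s = post.params[name]
    print(f"{name:22s} median {s.median:+.3f}  "
          f"95% CrI [{s.cri_low:+.3f}, {s.cri_high:+.3f}]  PSR {s.psr:.3f}")
call = classify_synchrony(post)
print(f"classification: parent-driven {call.parent_driven}, "
      f"child-driven {call.child_driven}")
```

prints

```
beta_child_to_parent   median +0.269  95% CrI [+0.152, +0.389]  PSR 1.000
beta_parent_to_child   median -0.093  95% CrI [-0.194, +0.006]  PSR 1.001
classification: parent-driven null, child-driven positive
```

The child-driven CrI excludes zero and brackets the true 0.3, so the dyad is
classified as showing positive child-driven synchrony; the parent-driven CrI
contains zero, correctly yielding a null call.

The spectral stage round-trips an analytically known signal: a 0.25 Hz
modulation of depth 40 ms has band power 40²/2 = 800 ms², and

```python
from dyadsync.validation import spectral_roundtrip_study
print(spectral_roundtrip_study(resp_freq=0.25))
```

prints

```
{'target_power_ms2': 800.0, 'mean_power_ms2': 789.435,
 'max_abs_log_error': 0.014, 'n_seconds': 237}
```

i.e. the beat → IBI → 4 Hz spline → multitaper pipeline recovers the target
power within 1.4% on every interior second.

A full cohort run from the shell:

```
dyadsync run-all --seed 1 --out results/demo
```

writes beat CSVs, a manifest with ground truth, per-participant RSA CSVs, a
stationarity screening report, posterior summaries, per-dyad synchrony calls,
and the cross-task agreement table (`agreement.json` / `agreement.csv`).

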