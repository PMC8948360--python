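# smlssi

Localization-precision bounds and maximum-likelihood localization for
**single-molecule localization by sequential structured illumination**
(SML-SSI) — the family of methods, including **MINFLUX** and **RASTMIN**,
that localize one fluorescent emitter by exposing it to a sequence of
doughnut beams whose intensity *minimum* is placed at known positions —
with support for **multiphoton** (superlinear) excitation.

It is aimed at microscopy researchers who want to ask, before building an
instrument: how precisely can a given excitation sequence localize an
emitter, how does that precision vary across the field of view, and what
does a two- or three-photon excitation nonlinearity buy?

## Model

A localization event is a sequence of K exposures with the beam minimum at
positions r_i spanning a pattern of size L. The emitter at r_E produces
expected counts λ_i ∝ I^c(r_E − r_i), where I is the doughnut intensity
(here I(ρ) = e·(ρ²/R²)·exp(−ρ²/R²), peak-normalized, R = λ/(2NA)) and c is
the excitation order (1 = linear, 2 = two-photon, 3 = three-photon;
fractional orders model effective superlinear photoswitching). Conditioning
the Poisson counts on the total photon budget N gives a multinomial with

    p_i = (SBR/(SBR+1)) · I^c(r_E − r_i) / Σ_j I^c(r_E − r_j) + 1/(K·(SBR+1)),

where SBR is the signal-to-background ratio. From p(r) the package computes

* the **Fisher information** F(r) = N Σ_i (1/p_i) ∇p_i ∇p_iᵀ and the
  **Cramér–Rao bound** σ_CRB(r) = √(tr F⁻¹ / 2), mapped over the field of
  view;
* the **maximum-likelihood estimate** of r_E from a count record, with
  Monte-Carlo validation of its efficiency against the bound;
* cross-order comparisons: the fold improvement in center precision between
  excitation orders and the equivalent photon-budget ratio (σ ∝ 1/√N holds
  exactly, so the two are related by a square).

## Worked example

```python
import numpy as np
from smlssi import (Scenario, make_beam_profile, minflux_sequence, crb_sigma,
                    center_improvement_ratio, photon_equivalence,
                    exposure_probabilities, sample_counts, mle_localize,
                    monte_carlo_precision)

beam = make_beam_profile(647.0, numerical_aperture=1.4)   # R = 231.07 nm
scn = Scenario(beam=beam, sequence=minflux_sequence(100.0),
               order=1.0, N=500, SBR=4.0)

print("sigma_CRB at center: %.3f nm" % crb_sigma(scn))
print("2p center improvement: %.3f" % center_improvement_ratio(scn, 1.0, 2.0))
print("2p photon equivalence: %.3f" % photon_equivalence(scn, 1.0, 2.0))
```

prints

```
sigma_CRB at center: 2.021 nm
2p center improvement: 2.000
2p photon equivalence: 0.250
```

i.e. one-photon MINFLUX with a 100 nm pattern, 500 detected photons and
SBR = 4 is bounded at ~2 nm precision at the pattern center; switching the
same beam to two-photon excitation doubles the center precision, which by
the 1/√N law is the same as needing a quarter of the photons. Localizing
one simulated count record and validating the estimator:

```python
rec = sample_counts(exposure_probabilities(scn), 500, seed=7)
print(mle_localize(rec, scn).summary())
print(monte_carlo_precision((0.0, 0.0), scn, repeats=1000, seed=1).as_dict())
```

```
Localization (multinomial MLE)
==============================================
method: minflux   K: 4   L: 100 nm
order c: 1   SBR: 4   photons: 500
----------------------------------------------
x_hat:    -2.202 nm   se(x):   2.027 nm
y_hat:     0.311 nm   se(y):   2.020 nm
log-likelihood: -600.0480
converged: True   iterations: 18
{'sigma_pooled_nm': 2.0696, ..., 'sigma_crb_nm': 2.021, 'ratio': 1.0241, ...}
```

The empirical spread of 1000 maximum-likelihood fits (2.07 nm) sits 2%
above the bound — the estimator is essentially efficient at this photon
count. The same machinery is scriptable from the shell:

```
smlssi map --method minflux --L 100 -N 500 --sbr 4 -c 1 --out runs/
smlssi compare --orders 1 2
smlssi validate --repeats 1000 --seed 1
```

`smlssi map` writes the σ_CRB map as CSV (+ JSON metadata, optionally
32-bit TIFF) with summary statistics (center/mean σ, coefficient of
variation, max/min contrast).

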