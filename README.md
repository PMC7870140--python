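# tcrdyn

Models and analyses of lifelong T cell clone-size dynamics: how the
power-law hierarchy of human T cell clone sizes is established by clonal
expansions during perinatal repertoire formation, and how slowly it is
reshaped by fluctuating clonal selection during adult life.

The package is aimed at computational immunologists working with bulk TCR
repertoire sequencing (clone tables of CDR3β read/UMI counts): it provides
the stochastic and analytic machinery to simulate repertoire dynamics,
fit clone-size scaling exponents robustly under subsampling, and date
clones statistically through their VDJ zero-insertion status.

## The model

**Repertoire formation.** Clones are recruited at rate θ with C₀ cells;
every cell dies at rate d and proliferates at the shared competitive rate
b₀/N, where N is the total cell count (mechanistically, consumption of a
common stimulus S = p/(q + kN)). The total size follows

    N(t) = (b₀ + θC₀)(1 − e^{−dt})/d,

and a clone recruited at time tᵢ grows deterministically as

    Cᵢ(t) = C₀ ((e^{dt} − 1)/(e^{dtᵢ} − 1))^{1/(1+γ)} e^{−d(t−tᵢ)},
    γ = θC₀/b₀,

≈ C₀ (t/tᵢ)^{1/(1+γ)} early on. Uniform recruitment times then yield a
rank–size power law, rank ∼ C^{−α}, with α = 1 + γ: clones founded during
the perinatal growth phase expand massively and dominate the hierarchy.

**Fluctuating selection.** During adult life the log clone size
x = log C performs Brownian motion with drift f₀ < 0 and variance 2σ²t
(geometric Brownian motion). The finite-time clone-size density for
uniformly aged clones has an erfc closed form whose x > 0 tail approaches
e^{−αx} with α = −f₀/σ², but only slowly when σ² is small — fluctuating
selection alone cannot explain the scaling seen already in young donors.

**Statistical clone dating.** Clones recombined before the enzyme TdT
turns on (fetal window, time t†) carry no inserted nucleotides at their
junctions. Starting from a hierarchy in which the r★ top clones carry the
fetal zero-insertion probability p₀₋ and the rest the adult value p₀₊,
diffusion by fluctuating selection relaxes the zero-insertion fraction at
rank r and age t along the sigmoid

    P₀(r, t) = (Δp₀/2) · erfc( (log(r/r★) + t/τ_d) / (2√(t/τ_d)) ) + p₀₊,

with reordering timescale τ_d = 1/(ασ)². Fitting (r★, τ_d, p₀₋, p₀₊) to
rank-binned zero-insertion fractions quantifies how long the early
imprint persists (about a decade).

**Inference tools.** Clone-size exponents are estimated by maximizing the
discrete power-law likelihood with a Hurwitz-zeta normalization over
clones above a trimming threshold C_min = 16 reads, which suppresses the
bias that Poisson subsampling induces at small sizes; σ² is estimated
from longitudinal data by regressing the variance of log-foldchanges on
the time difference (slope 2σ², with an intercept absorbing sampling
noise 2σ_S²).

## Worked example

Simulate five years of repertoire formation at γ = 0.1 (mean-field
competition), subsample reads, and recover the exponent:

```python
import numpy as np
from tcrdyn import FormationParams, SimConfig
from tcrdyn.simulate import simulate_meanfield
from tcrdyn.powerlaw import subsample_poisson, fit_exponent_mle

params = FormationParams(b0=1e5, d=0.2, theta=1e4)   # gamma = 0.1
cfg = SimConfig(params=params, t_end=5.0, record_times=(5.0,),
                seed=0, mode="meanfield")
snapshot = simulate_meanfield(cfg)[0]
print(f"clones alive at 5 y: {snapshot.n_clones}, cells: {snapshot.N:.3g}")
sample = subsample_poisson(snapshot.sizes, 1e6, seed=1)
fit = fit_exponent_mle(sample, c_min=16)
print(f"alpha_hat = {fit.alpha_hat:.3f} +/- {fit.se:.3f}"
      "  (theory: 1 + gamma = 1.10)")
```

prints

```
clones alive at 5 y: 39286, cells: 2.32e+05
alpha_hat = 1.140 +/- 0.012  (theory: 1 + gamma = 1.10)
```

i.e. ~39k surviving clones whose sampled tail follows the predicted
power law (the small upward shift from 1.10 is the expected
finite-scale systematic of desk-sized runs; see `docs/methods.md`).
The dating sigmoid at the cohort-scale fitted parameters shows how
enrichment persists among top clones and decays over decades:

```python
from tcrdyn import RelaxationParams
from tcrdyn.theory import zero_insertion_profile
p = RelaxationParams(r_star=1.2e4, tau_d=9.1, p0_minus=0.07, p0_plus=0.02)
for t in (5, 25, 65):
    print(f"age {t:2d} y: P0(rank 100) = {zero_insertion_profile(100, t, p):.4f}, "
          f"P0(rank 1e6) = {zero_insertion_profile(1e6, t, p):.4f}")
```

```
age  5 y: P0(rank 100) = 0.0700, P0(rank 1e6) = 0.0200
age 25 y: P0(rank 100) = 0.0604, P0(rank 1e6) = 0.0201
age 65 y: P0(rank 100) = 0.0333, P0(rank 1e6) = 0.0201
```

The top-ranked clones of a 25-year-old still carry nearly the fetal
zero-insertion fraction, while deep ranks sit at the adult value — the
signature of early-life imprinting.

A command-line surface wraps the same library:
`tcrdyn simulate | cohort | fit-powerlaw | enrich | longitudinal | theory`,
each taking `--config` (YAML), `--seed` and `--out`.

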