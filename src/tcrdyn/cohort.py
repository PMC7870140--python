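"""Synthetic-data generation: simulated cross-sectional cohorts, synthetic
longitudinal trajectories, and pure discrete power-law samples.

The cohort generator emulates the memory T cell compartment of individuals
of different ages under the combined effect of (i) deterministic clonal
expansion during perinatal repertoire formation and (ii) fluctuating clonal
selection during adult life, with zero-insertion labels that mimic the
switch in VDJ recombination statistics when the enzyme TdT turns on during
fetal development.  Per individual of age T, the direct sampling scheme is:

1. number of clones = round(theta * T)  (round-half-even);
2. recruitment times t_i uniform on [0, T];
3. zero-insertion flag Bernoulli(p0(t_i)), where p0 is the fraction of
   zero-insertion clones in the naive pool at the time of recruitment
   (:func:`p0_of_time`);
4. log sizes normal with mean
   ``-d(T-t_i) + log((e^{dT}-1)/(e^{d t_i}-1))/(1+gamma) - sigma2*(T-t_i)``
   and variance ``2*sigma2*(T-t_i)`` — the deterministic growth law plus
   the geometric-Brownian propagator; the ``-sigma2*(T-t_i)`` mean shift is
   the lognormal correction that keeps the expected linear-scale size equal
   to the deterministic law;
5. reads per clone Poisson(n_sample * C_i / sum C), zero-read clones
   dropped.

Demographic (birth-death) noise is deliberately ignored here: memory
clones are large enough that selection fluctuations dominate.  Relative to
real cohort data the generator omits, among other things, sequence-level
receptor generation, convergent recombination, phenotype structure and
CMV/sex covariates.
"""

from __future__ import annotations

import warnings

import numpy as np

from .simulate import simulate_fluctuating
from .types import (
    CloneSizeSample,
    CohortParams,
    CohortSample,
    FluctParams,
    TrajectorySet,
)
from .powerlaw import hurwitz_zeta, poisson_sample_counts

__all__ = [
    "p0_of_time",
    "latent_log_sizes",
    "sample_individual",
    "sample_cohort",
    "draw_ages",
    "generate_longitudinal",
    "generate_zipf_sample",
]


def p0_of_time(t, params: CohortParams):
    """Zero-insertion probability in the naive pool at time ``t`` (years).

    Before TdT expression turns on at ``t_dagger`` every new clone carries
    the fetal statistics, ``p0_minus``.  Afterwards the pool is a mixture
    of the ``theta*t_dagger`` clones made before the switch and the
    ``theta*(t - t_dagger)`` made after, so the fraction dilutes as::

        p0(t) = p0_minus * (t_dagger / t) + p0_plus * (1 - t_dagger / t)

    which interpolates from ``p0_minus`` at ``t_dagger`` to ``p0_plus`` as
    t -> infinity while staying inside [p0_plus, p0_minus].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    w = np.where(t > params.t_dagger, params.t_dagger / np.maximum(t, params.t_dagger), 1.0)
    return params.p0_minus * w + params.p0_plus * (1.0 - w)


def latent_log_sizes(ti, T: float, params: CohortParams, rng: np.random.Generator):
    """Latent log clone sizes at age ``T`` for recruitment times ``ti``:
    deterministic growth plus the Gaussian fluctuating-selection propagator."""
    ti = np.asarray(ti, dtype=float)
    d, g, s2 = params.d, params.gamma, params.sigma2
    dt = T - ti
    mean = (
        -d * dt
        + np.log(np.expm1(d * T) / np.expm1(d * ti)) / (1.0 + g)
        - s2 * dt
    )
    return rng.normal(mean, np.sqrt(2.0 * s2 * dt))


def sample_individual(
    params: CohortParams,
    age: float,
    seed: int | np.random.Generator,
    return_latent: bool = False,
):
    """One synthetic individual: sampled read counts with aligned
    zero-insertion labels, by the direct sampling scheme above.

    With ``return_latent=True`` also returns a dict with the recruitment
    times, zero-insertion flags and latent sizes of *all* recruited clones
    (before read sampling), for diagnostics.
    """
    if not age > 0:
        raise ValueError("age must be > 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n_clones = int(np.round(params.theta * age))  # numpy rounds half to even
    if n_clones < 1:
        warnings.warn(
            f"theta*age = {params.theta * age:.3g} < 1: empty individual",
            stacklevel=2,
        )
        sample = CohortSample(
            individual_id=0,
            age=age,
            counts=np.empty(0, dtype=np.int64),
            zero_insertions=np.empty(0, dtype=bool),
        )
        if return_latent:
            empty = np.empty(0)
            return sample, {"t_recruit": empty, "zero": empty.astype(bool), "sizes": empty}
        return sample
    ti = rng.uniform(0.0, age, size=n_clones)
    ti = np.maximum(ti, 1e-12)  # growth law diverges at ti = 0 exactly
    zero = rng.random(n_clones) < p0_of_time(ti, params)
    x = latent_log_sizes(ti, age, params, rng)
    sizes = np.exp(x)
    counts = poisson_sample_counts(sizes, params.n_sample, rng)
    keep = counts > 0
    sample = CohortSample(
        individual_id=0,
        age=age,
        counts=counts[keep],
        zero_insertions=zero[keep],
    )
    if return_latent:
        return sample, {"t_recruit": ti, "zero": zero, "sizes": sizes}
    return sample


def draw_ages(params: CohortParams, n_individuals: int, seed: int) -> np.ndarray:
    """Cohort ages, uniform on ``params.age_range`` (clipped away from 0)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    lo, hi = params.age_range
    return np.maximum(rng.uniform(lo, hi, size=n_individuals), 1e-6)


def sample_cohort(
    params: CohortParams,
    n_individuals: int,
    seed: int,
) -> list[CohortSample]:
    """Cross-sectional cohort with ages uniform on ``params.age_range``.

    Each individual draws from a child random stream, so a cohort is
    reproducible under its root seed regardless of evaluation order.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    ages = draw_ages(params, n_individuals, seed)
    samples = []
    for i in range(n_individuals):
        child = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, i))
        )
        s = sample_individual(params, float(ages[i]), child)
        s.individual_id = i
        samples.append(s)
    return samples


def generate_longitudinal(
    params: FluctParams,
    n_clones: int,
    timepoints,
    sampling_noise_var: float = 0.0,
    seed: int = 0,
    x0=None,
) -> TrajectorySet:
    """Synthetic longitudinal clone-size trajectories.

    Latent log sizes follow the geometric-Brownian fluctuating-selection
    model (:func:`tcrdyn.simulate.simulate_fluctuating`); the observed log
    size adds independent Gaussian noise of variance ``sampling_noise_var``
    per timepoint, emulating sample-to-sample measurement variability.
    Counts are the rounded exponentials of the observed log sizes; initial
    sizes default to log-uniform between 1e3 and 1e5 so that rounding is
    negligible for the large clones these analyses target.
    """
    if sampling_noise_var < 0:
        raise ValueError("sampling_noise_var must be >= 0")
    times = np.asarray(timepoints, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = rng.uniform(np.log(1e3), np.log(1e5), size=n_clones)
    else:
        x0 = np.broadcast_to(np.asarray(x0, dtype=float), (n_clones,)).copy()
    x = simulate_fluctuating(params, x0, times, rng)
    x_obs = x + np.sqrt(sampling_noise_var) * rng.standard_normal(x.shape)
    counts = np.rint(np.exp(x_obs)).astype(np.int64)
    return TrajectorySet(
        clone_ids=np.arange(n_clones),
        times=times,
        counts=counts,
    )


def _zeta_tail_quantile(s: float, u: float, z1: float, k_lo: int) -> int:
    """Smallest k >= k_lo with P(C <= k) >= u for the zeta(s) law, by
    doubling plus bisection on the Hurwitz tail."""
    # P(C > k) = zeta(s, k+1)/z1
    hi = max(2 * k_lo, 2)
    while hurwitz_zeta(s, hi + 1) / z1 > 1.0 - u:
        hi *= 2
    lo = k_lo
    while lo < hi:
        mid = (lo + hi) // 2
        if hurwitz_zeta(s, mid + 1) / z1 <= 1.0 - u:
            hi = mid
        else:
            lo = mid + 1
    return lo


def generate_zipf_sample(
    alpha: float,
    n_clones: int,
    seed: int | np.random.Generator,
    _table_max: int = 1_000_000,
) -> CloneSizeSample:
    """I.i.d. clone sizes from the discrete power law (zeta distribution)
    with rank exponent ``alpha``: ``P(C) = C^{-(1+alpha)} / zeta(1+alpha)``
    on C >= 1, via inverse transform on a tabulated CDF with an exact
    Hurwitz-tail fallback above the table."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    s = 1.0 + alpha
    z1 = float(hurwitz_zeta(s, 1))
    support = np.arange(1, _table_max + 1, dtype=float)
    cdf = np.cumsum(support**-s) / z1
    u = rng.random(n_clones)
    idx = np.searchsorted(cdf, u, side="left")
    counts = idx + 1
    overflow = idx >= _table_max
    if np.any(overflow):
        counts[overflow] = [
            _zeta_tail_quantile(s, ui, z1, _table_max + 1) for ui in u[overflow]
        ]
    return CloneSizeSample(counts=counts.astype(np.int64))
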