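"""Rank-size statistics and subsampling-robust discrete power-law inference.

The tail of T cell clone-size distributions follows Zipf-like scaling,
rank ~ C^(-alpha).  Because only a small fraction of all T cells is
sequenced, the small-size end of a sampled distribution is strongly
distorted (Poisson subsampling flattens it), while the tail slope is
preserved.  The maximum-likelihood estimator here therefore trims clones
below a minimal size ``c_min`` (default 16 reads) and maximizes the
discrete (Hurwitz-zeta) power-law likelihood

    L(alpha) = -M * log zeta(1 + alpha, c_min) - (1 + alpha) * sum_i log C_i

over the ``M`` retained clones, where ``zeta(s, k) = sum_{n>=k} n^{-s}``
is the Hurwitz zeta function (the "incomplete" Riemann zeta).  ``alpha``
here is the rank exponent; the corresponding size-density exponent is
``1 + alpha``.  The likelihood applies to integer counts only; normalized
(real-valued) clone sizes are for plotting and cross-age comparison, never
for the MLE.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta as _hurwitz_zeta

from .types import CloneSizeSample, ExponentFit

__all__ = [
    "rank_size",
    "fit_exponent_mle",
    "subsample_poisson",
    "normalize_clone_sizes",
]

ALPHA_BOUNDS = (0.05, 10.0)
M_FLOOR = 30


def rank_size(sample: CloneSizeSample, normalize: bool = False):
    """Rank-size (Zipf) coordinates: sizes sorted descending, ranks 1..M.

    Ties are broken by stable input order.  With ``normalize=True`` sizes
    are divided by the total read count and by the sample's memory-cell
    fraction (a proxy for the phenotype composition of blood at that age);
    a missing memory fraction falls back to 1.0 with a warning.
    """
    if sample.n_clones == 0:
        raise ValueError("cannot rank an empty sample")
    order = np.argsort(-sample.counts, kind="stable")
    sizes = sample.counts[order].astype(float)
    if normalize:
        mf = sample.memory_fraction
        if mf is None:
            warnings.warn(
                "normalize requested without memory_fraction; using 1.0",
                stacklevel=2,
            )
            mf = 1.0
        sizes = sizes / sample.total_reads / mf
    ranks = np.arange(1, len(sizes) + 1)
    return ranks, sizes


def hurwitz_zeta(s, k):
    """zeta(s, k) = sum_{n >= k} n^{-s} for s > 1, integer k >= 1."""
    return _hurwitz_zeta(s, k)


def fit_exponent_mle(
    sample: CloneSizeSample,
    c_min: int = 16,
    m_floor: int = M_FLOOR,
) -> ExponentFit:
    """Trimmed maximum-likelihood estimate of the rank exponent alpha.

    Maximizes the discrete power-law likelihood over clones with count
    >= ``c_min`` by bounded scalar optimization on ``alpha in (0.05, 10]``
    (tolerance 1e-6).  The standard error comes from the observed Fisher
    information, i.e. the numerical curvature of the log-likelihood at the
    optimum.  A fit whose optimum sticks to a bound (e.g. for degenerate
    input where all counts equal ``c_min``) is flagged via ``at_bound``.
    """
    counts = sample.counts[sample.counts >= c_min]
    m = len(counts)
    if m < m_floor:
        raise ValueError(
            f"only {m} clones with count >= c_min={c_min}; "
            f"need at least m_floor={m_floor} for a meaningful fit"
        )
    sum_log = float(np.log(counts).sum())

    def negll(alpha: float) -> float:
        return m * np.log(hurwitz_zeta(1.0 + alpha, c_min)) + (1.0 + alpha) * sum_log

    res = minimize_scalar(
        negll,
        bounds=ALPHA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    alpha_hat = float(res.x)
    at_bound = (
        alpha_hat - ALPHA_BOUNDS[0] < 1e-4 or ALPHA_BOUNDS[1] - alpha_hat < 1e-4
    )
    # observed Fisher information from central-difference curvature
    h = 1e-4
    curv = (negll(alpha_hat + h) - 2.0 * res.fun + negll(alpha_hat - h)) / h**2
    se = float(1.0 / np.sqrt(curv)) if curv > 0 else np.nan
    return ExponentFit(
        alpha_hat=alpha_hat,
        se=se,
        c_min=int(c_min),
        m_used=m,
        at_bound=at_bound,
        log_likelihood=-float(res.fun),
    )


def poisson_sample_counts(true_sizes, n_reads: float, rng: np.random.Generator):
    """Per-clone read counts from Poisson sampling at a target depth.

    Each clone receives ``Poisson(n_reads * C_i / N)`` reads, so the total
    sampled read count is Poisson with mean ``n_reads``.  Returns the full
    count vector including zeros (clones missed by sequencing).
    """
    true_sizes = np.asarray(true_sizes, dtype=float)
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0 or true_sizes.size == 0:
        return np.zeros(len(true_sizes), dtype=np.int64)
    lam = n_reads * true_sizes / true_sizes.sum()
    return rng.poisson(lam)


def subsample_poisson(
    true_sizes,
    n_reads: float,
    seed: int | np.random.Generator,
) -> CloneSizeSample:
    """Poisson-subsample latent clone sizes to sequencing depth ``n_reads``,
    dropping clones that receive zero reads."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    counts = poisson_sample_counts(true_sizes, n_reads, rng)
    return CloneSizeSample(counts=counts[counts > 0])


def normalize_clone_sizes(
    sample: CloneSizeSample,
    memory_fraction_fn: Callable[[float], float] | None = None,
):
    """Clone sizes as read fractions, optionally divided by the
    age-dependent memory-phenotype fraction.

    Two samples of identical clonal composition taken at different
    sequencing depths collapse onto identical normalized sizes.
    """
    fraction = 1.0
    if memory_fraction_fn is not None:
        if sample.age is None:
            raise ValueError("age-dependent normalization requires sample.age")
        fraction = float(memory_fraction_fn(sample.age))
    if not 0 < fraction <= 1:
        raise ValueError(f"memory fraction must be in (0, 1], got {fraction}")
    return sample.counts / sample.total_reads / fraction
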