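"""Zero-insertion enrichment analysis.

Clones whose receptors carry no inserted nucleotides at either junction are
strongly over-represented among clones generated before TdT expression
begins in fetal development, so the fraction of zero-insertion clones as a
function of clone-size rank and donor age dates the large clones of the
hierarchy.  This module bins that fraction (:func:`bin_zero_fraction`),
fits the four-parameter relaxation sigmoid
(:func:`tcrdyn.theory.zero_insertion_profile`) by weighted least squares
(:func:`fit_relaxation`), rescales the data onto the universal erfc curve
(:func:`rescale_collapse`), and provides the case-resampling bootstrap used
for regression confidence intervals (:func:`bootstrap_regression`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc

from .theory import collapse_abscissa
from .types import CohortSample, RelaxationFitResult

__all__ = [
    "bin_zero_fraction",
    "fit_relaxation",
    "rescale_collapse",
    "bootstrap_regression",
]

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "age_mid",
    "rank_lo",
    "rank_hi",
    "rank_mid",
    "fraction_zero",
    "se",
    "n_clones",
]


def bin_zero_fraction(
    samples: list[CohortSample],
    rank_bin_width: int = 500,
    age_bins=None,
) -> pd.DataFrame:
    """Fraction of zero-insertion clones pooled by (age bin, rank bin).

    Within each individual, clones are ranked by descending read count
    (ties keep stable input order) and assigned to non-overlapping rank
    bins 1-500, 501-1000, ... (width configurable).  Clones are then pooled
    over individuals within age bins (default: 10-year brackets covering
    the cohort) and the fraction with zero insertions is reported with its
    binomial standard error sqrt(p(1-p)/n); empty cells are dropped.  For
    cells where the fraction is exactly 0 or 1 the SE uses a half-count
    pseudocount floor so downstream weights stay finite.
    """
    age_bins, a_idx, Z, T = _per_individual_histograms(
        samples, rank_bin_width, age_bins
    )
    return _table_from_histograms(
        age_bins, a_idx, Z, T, rank_bin_width, np.arange(len(samples))
    )


def _per_individual_histograms(samples, rank_bin_width, age_bins):
    """Per-individual (zero-insertion, total) clone counts per rank bin,
    plus each individual's age-bin index — the sufficient statistics for
    pooled enrichment tables (and their case-resampling bootstrap)."""
    if not samples:
        raise ValueError("no samples given")
    ages = np.array([s.age for s in samples])
    if age_bins is None:
        hi = 10.0 * np.ceil(ages.max() / 10.0 + 1e-9)
        age_bins = np.arange(0.0, max(hi, 10.0) + 1e-9, 10.0)
    age_bins = np.asarray(age_bins, dtype=float)
    a_idx = np.clip(
        np.searchsorted(age_bins, ages, side="right") - 1, 0, len(age_bins) - 2
    )
    n_rb = max(
        (s.n_clones + rank_bin_width - 1) // rank_bin_width for s in samples
    )
    n_rb = max(n_rb, 1)
    Z = np.zeros((len(samples), n_rb), dtype=np.int64)
    T = np.zeros((len(samples), n_rb), dtype=np.int64)
    for i, s in enumerate(samples):
        if s.n_clones == 0:
            continue
        order = np.argsort(-s.counts, kind="stable")  # stable ties
        zero_sorted = s.zero_insertions[order].astype(np.int64)
        rbin = np.arange(s.n_clones) // rank_bin_width
        Z[i, : rbin[-1] + 1] = np.bincount(rbin, weights=zero_sorted).astype(np.int64)
        T[i, : rbin[-1] + 1] = np.bincount(rbin)
    return age_bins, a_idx, Z, T


def _table_from_histograms(age_bins, a_idx, Z, T, rank_bin_width, indices):
    """Pool per-individual histograms (for the given individuals, possibly
    with repeats) into an enrichment table."""
    n_age = len(age_bins) - 1
    n_rb = Z.shape[1]
    zsum = np.zeros((n_age, n_rb))
    tsum = np.zeros((n_age, n_rb))
    np.add.at(zsum, a_idx[indices], Z[indices])
    np.add.at(tsum, a_idx[indices], T[indices])
    a_grid, r_grid = np.nonzero(tsum > 0)
    n = tsum[a_grid, r_grid]
    p = zsum[a_grid, r_grid] / n
    # pseudocount SE floor for degenerate cells
    p_floor = np.clip(p, 0.5 / n, 1.0 - 0.5 / n)
    se = np.sqrt(p_floor * (1.0 - p_floor) / n)
    out = pd.DataFrame(
        {
            "age_mid": (age_bins[a_grid] + age_bins[a_grid + 1]) / 2.0,
            "rank_lo": r_grid * rank_bin_width + 1,
            "rank_hi": (r_grid + 1) * rank_bin_width,
            "rank_mid": r_grid * rank_bin_width + (rank_bin_width + 1) / 2.0,
            "fraction_zero": p,
            "se": se,
            "n_clones": n.astype(np.int64),
        }
    )
    n_dropped = n_age * n_rb - len(out)
    if n_dropped > 0:
        logger.info("dropped %d empty (age, rank) cells", n_dropped)
    return out.sort_values(["age_mid", "rank_lo"], ignore_index=True)


def _sigmoid_residuals(z, ranks, ages, fracs, weights):
    # smooth unclamped model so the optimizer sees no kinks; bounds keep the
    # final estimate admissible
    log_r_star, log_tau_d, p0m, p0p = z
    s = ages / np.exp(log_tau_d)
    u = (np.log(ranks) - log_r_star + s) / (2.0 * np.sqrt(s))
    pred = 0.5 * (p0m - p0p) * erfc(u) + p0p
    return weights * (fracs - pred)


def fit_relaxation(
    table: pd.DataFrame,
    spec_error: float = 2e-3,
    n_starts: int = 6,
    seed: int = 0,
) -> RelaxationFitResult:
    """Weighted least-squares fit of (r*, tau_d, p0-, p0+) to a binned
    enrichment table.

    Each cell is weighted by ``1/(se + spec_error)^2``, where ``spec_error``
    is a fixed model-specification error added to the empirical binomial SE
    (default 2e-3); rank and age enter as bin mid-values.  ``r*`` and
    ``tau_d`` are log-transformed internally for positivity, and the
    optimizer (trust-region reflective nonlinear least squares) is run from
    ``n_starts`` starting points, keeping the best.  Standard errors come
    from the Jacobian at the optimum scaled by the reduced chi-square, with
    the delta method mapping the log-parameters back.
    """
    required_rows = 8
    if len(table) < required_rows or table["age_mid"].nunique() < 2:
        raise ValueError(
            f"need >= {required_rows} rows spanning >= 2 age bins, got "
            f"{len(table)} rows / {table['age_mid'].nunique()} age bins"
        )
    w = 1.0 / (table["se"].to_numpy() + spec_error)
    ranks = table["rank_mid"].to_numpy(dtype=float)
    ages = table["age_mid"].to_numpy(dtype=float)
    fracs = table["fraction_zero"].to_numpy()
    p_lo, p_hi = float(fracs.min()), float(fracs.max())
    rng = np.random.default_rng(seed)
    max_rank = float(table["rank_hi"].max())
    max_age = float(table["age_mid"].max())
    starts = [
        np.array([np.log(max(max_rank / 20.0, 2.0)), np.log(max_age / 4.0 + 1.0),
                  p_hi, p_lo])
    ]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    rng.uniform(np.log(2.0), np.log(max_rank)),
                    rng.uniform(np.log(0.5), np.log(4.0 * max_age + 2.0)),
                    min(p_hi * rng.uniform(0.8, 1.5) + 1e-3, 1.0),
                    p_lo * rng.uniform(0.5, 1.2) + 1e-4,
                ]
            )
        )
    lower = [0.0, np.log(1e-3), 0.0, 0.0]
    upper = [np.log(1e9), np.log(1e4), 1.0, 1.0]
    best = None
    for z0 in starts:
        z0 = np.clip(z0, lower, upper)
        try:
            res = least_squares(
                _sigmoid_residuals,
                z0,
                bounds=(lower, upper),
                args=(ranks, ages, fracs, w),
                method="trf",
            )
        except Exception:  # noqa: BLE001 - keep trying other starts
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("relaxation fit failed to converge from any start")
    z = best.x
    wrss = float(2.0 * best.cost)
    dof = max(len(table) - 4, 1)
    s2 = wrss / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se_z = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover - singular Jacobian
        se_z = np.full(4, np.nan)
    r_star, tau_d = float(np.exp(z[0])), float(np.exp(z[1]))
    return RelaxationFitResult(
        r_star=r_star,
        r_star_se=r_star * float(se_z[0]),  # delta method for log-params
        tau_d=tau_d,
        tau_d_se=tau_d * float(se_z[1]),
        p0_minus=float(z[2]),
        p0_minus_se=float(se_z[2]),
        p0_plus=float(z[3]),
        p0_plus_se=float(se_z[3]),
        wrss=wrss,
        n_points=len(table),
    )


def bootstrap_relaxation(
    samples: list[CohortSample],
    rank_bin_width: int = 500,
    age_bins=None,
    spec_error: float = 2e-3,
    n_boot: int = 50,
    seed: int = 0,
    ci_level: float = 0.95,
):
    """Relaxation fit with case-resampling bootstrap CIs over individuals.

    The weighted-least-squares standard errors treat binned cells as
    independent binomial draws, which understates cohort-level variability
    (and any residual model misspecification); resampling whole individuals
    is the appropriate uncertainty for parameter-recovery statements.
    Returns ``(fit, ci)`` where ``ci`` maps parameter names to percentile
    intervals.
    """
    age_bins_, a_idx, Z, T = _per_individual_histograms(
        samples, rank_bin_width, age_bins
    )
    n = len(samples)
    full_idx = np.arange(n)
    table = _table_from_histograms(age_bins_, a_idx, Z, T, rank_bin_width, full_idx)
    fit = fit_relaxation(table, spec_error=spec_error, seed=seed)
    rng = np.random.default_rng(seed)
    draws = {k: [] for k in ("r_star", "tau_d", "p0_minus", "p0_plus")}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        btab = _table_from_histograms(age_bins_, a_idx, Z, T, rank_bin_width, idx)
        try:
            bfit = fit_relaxation(btab, spec_error=spec_error, seed=seed, n_starts=2)
        except (ValueError, RuntimeError):
            continue
        for k in draws:
            draws[k].append(getattr(bfit, k))
    q = (1.0 - ci_level) / 2.0
    ci = {
        k: tuple(np.quantile(v, [q, 1.0 - q])) for k, v in draws.items() if v
    }
    return fit, ci


def rescale_collapse(table: pd.DataFrame, fit: RelaxationFitResult):
    """Collapse binned enrichment data onto the universal sigmoid.

    Returns ``(points, curve)``: ``points`` is a DataFrame with the
    rescaled abscissa ``u = (log(r/r*) + t/tau_d) / (2*sqrt(t/tau_d))``,
    the measured fraction and its SE; ``curve`` samples the reference
    ``y(u) = (dp0/2)*erfc(u) + p0_plus`` on a regular grid spanning the
    data.  The abscissa is invariant under joint rescaling of r and r*.
    """
    params = fit.params
    u = collapse_abscissa(
        table["rank_mid"].to_numpy(), table["age_mid"].to_numpy(), params
    )
    points = pd.DataFrame(
        {
            "u": u,
            "fraction_zero": table["fraction_zero"].to_numpy(),
            "se": table["se"].to_numpy(),
        }
    )
    grid = np.linspace(u.min() - 0.5, u.max() + 0.5, 400)
    curve = pd.DataFrame(
        {
            "u": grid,
            "fraction_zero": 0.5 * params.delta_p0 * erfc(grid) + params.p0_plus,
        }
    )
    return points, curve


def bootstrap_regression(
    x,
    y,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
):
    """Ordinary least squares with case-resampling bootstrap intervals.

    Returns ``(slope, intercept, slope_ci, intercept_ci)`` where the CIs
    are percentile intervals over ``n_boot`` resampled refits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")

    def ols(xs, ys):
        xm = xs.mean(axis=-1, keepdims=True)
        ym = ys.mean(axis=-1, keepdims=True)
        sxx = ((xs - xm) ** 2).sum(axis=-1)
        sxy = ((xs - xm) * (ys - ym)).sum(axis=-1)
        slope = sxy / sxx
        intercept = ym[..., 0] - slope * xm[..., 0]
        return slope, intercept

    slope, intercept = ols(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    ok = np.ptp(bx, axis=1) > 0  # degenerate resamples dropped
    bslope, bint = ols(bx[ok], by[ok])
    q = (1.0 - ci_level) / 2.0
    slope_ci = tuple(np.quantile(bslope, [q, 1.0 - q]))
    intercept_ci = tuple(np.quantile(bint, [q, 1.0 - q]))
    return float(slope), float(intercept), slope_ci, intercept_ci
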