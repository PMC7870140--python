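"""Longitudinal clone-size fluctuation analysis.

Under the fluctuating clonal selection model, the variance of log-foldchanges
of clone frequency grows linearly in the time difference, with slope 2σ²;
sample-to-sample measurement variability adds a constant 2σ_S².  Fitting a
line with intercept to the empirical variance curve therefore estimates both
the growth-rate fluctuation strength σ² (slope/2) and the sampling variance
σ_S² (intercept/2).  Companion analysis: the rank-origin composition of the
largest clones at later timepoints, showing how many of them were already
large initially.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .enrichment import bootstrap_regression
from .types import FluctuationEstimate, TrajectorySet

__all__ = [
    "logfold_variance_curve",
    "estimate_fluctuation_strength",
    "rank_origin_composition",
]


def logfold_variance_curve(
    ts: TrajectorySet,
    ref_index: int = 1,
    top_n: int = 250,
    detect_index: int = 0,
    min_clones: int = 20,
) -> pd.DataFrame:
    """Variance of log clone-frequency foldchanges versus time difference.

    The analysis restricts to the ``top_n`` largest clones at the reference
    timepoint (by default the second sample) that were also detected at the
    earliest timepoint — clones absent initially are likely recent
    expansions whose transient dynamics would confound the long-term
    fluctuation estimate, so they are excluded.  Frequencies (count/total
    reads per timepoint) are used inside the foldchanges to remove depth
    variation.  Returns a table of (dt, variance, n_clones) for every
    timepoint after the reference.
    """
    k = len(ts.times)
    if not 0 <= ref_index < k - 1:
        raise ValueError(f"ref_index {ref_index} out of range for {k} timepoints")
    freq = ts.frequencies
    detected_all = ts.detected.all(axis=1)
    eligible = detected_all & ts.detected[:, detect_index]
    order = np.argsort(-freq[:, ref_index] * eligible, kind="stable")
    chosen = order[:top_n]
    chosen = chosen[eligible[chosen]]
    if len(chosen) < min_clones:
        raise ValueError(
            f"only {len(chosen)} eligible clones (detected at timepoints "
            f"{detect_index} and all others); need >= {min_clones}"
        )
    logf = np.log(freq[chosen][:, ref_index + 1 :] / freq[chosen][:, [ref_index]])
    dts = ts.times[ref_index + 1 :] - ts.times[ref_index]
    return pd.DataFrame(
        {
            "dt": dts,
            "variance": logf.var(axis=0, ddof=1),
            "n_clones": len(chosen),
        }
    )


def estimate_fluctuation_strength(
    curve: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> FluctuationEstimate:
    """Growth-rate fluctuation strength σ² from the variance curve.

    Ordinary least squares of variance on dt with intercept; σ̂² = slope/2
    and σ̂_S² = intercept/2, with a case-resampling bootstrap interval on
    the slope.  A negative slope is clipped to zero (with a warning flag),
    as is a negative intercept.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 time differences")
    X = sm.add_constant(curve["dt"].to_numpy())
    fit = sm.OLS(curve["variance"].to_numpy(), X).fit()
    intercept, slope = fit.params
    _, _, slope_ci, _ = bootstrap_regression(
        curve["dt"].to_numpy(), curve["variance"].to_numpy(), n_boot=n_boot, seed=seed
    )
    clipped = False
    if slope < 0 or intercept < 0:
        warnings.warn(
            "negative variance-curve slope or intercept clipped to 0", stacklevel=2
        )
        clipped = True
    return FluctuationEstimate(
        sigma2_hat=max(slope, 0.0) / 2.0,
        sampling_var_hat=max(intercept, 0.0) / 2.0,
        slope=float(slope),
        intercept=float(intercept),
        slope_ci=slope_ci,
        clipped=clipped,
    )


def rank_origin_composition(
    ts: TrajectorySet,
    top_n: int = 1000,
    origin_bins=(1000, 10_000, 100_000),
) -> pd.DataFrame:
    """Where were today's largest clones at the earliest timepoint?

    For every timepoint after the first, the ``top_n`` largest clones (by
    frequency) are classified by their clone-size rank at the earliest
    timepoint into bins with the given upper edges, with one extra bin for
    ranks beyond the last edge and an ``ND`` (not detected) category for
    clones with zero reads initially.  Fractions sum to one per timepoint.
    """
    if len(ts.times) < 2:
        raise ValueError("need at least 2 timepoints")
    freq = ts.frequencies
    edges = list(origin_bins)
    labels = []
    lo = 1
    for e in edges:
        labels.append(f"{lo}-{e}")
        lo = e + 1
    labels.append(f">{edges[-1]}")
    labels.append("ND")
    # ranks at the earliest timepoint (only detected clones get a rank)
    first = freq[:, 0]
    order0 = np.argsort(-first, kind="stable")
    rank0 = np.empty(len(first), dtype=np.int64)
    rank0[order0] = np.arange(1, len(first) + 1)
    detected0 = ts.detected[:, 0]
    rows = []
    for j in range(1, len(ts.times)):
        top = np.argsort(-freq[:, j], kind="stable")[:top_n]
        top = top[ts.detected[top, j]]
        counts = dict.fromkeys(labels, 0)
        for i in top:
            if not detected0[i]:
                counts["ND"] += 1
                continue
            r = rank0[i]
            for e, lab in zip(edges, labels):
                if r <= e:
                    counts[lab] += 1
                    break
            else:
                counts[f">{edges[-1]}"] += 1
        total = max(len(top), 1)
        for lab in labels:
            rows.append(
                {
                    "time": ts.times[j],
                    "origin_bin": lab,
                    "fraction": counts[lab] / total,
                    "n_clones": total,
                }
            )
    return pd.DataFrame(rows)
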