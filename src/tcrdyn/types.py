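"""Domain types shared across the package.

Parameter bundles are frozen dataclasses with validation in ``__post_init__``;
derived quantities (``gamma``, ``alpha``) are properties so they can never get
out of sync with the primary fields.  Repertoire containers hold numpy arrays
rather than per-clone objects for efficiency, but expose record-level views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "FormationParams",
    "FluctParams",
    "CytokineParams",
    "RelaxationParams",
    "CohortParams",
    "CloneRecord",
    "RepertoireSnapshot",
    "SimConfig",
    "CloneSizeSample",
    "ExponentFit",
    "CohortSample",
    "RelaxationFitResult",
    "TrajectorySet",
    "FluctuationEstimate",
]


@dataclass(frozen=True)
class FormationParams:
    """Rates of the repertoire-formation (birth-death-immigration) model.

    Parameters
    ----------
    b0 : float
        Total proliferation rate of the compartment (cells/year).  The
        per-cell proliferation rate is ``b0 / N`` where ``N`` is the total
        number of cells, encoding competition for shared resources.
    d : float
        Per-cell death rate (1/year).
    theta : float
        Recruitment rate of new clones (clones/year).
    C0 : int
        Number of cells a clone starts with at recruitment.
    """

    b0: float
    d: float
    theta: float
    C0: int = 1

    def __post_init__(self) -> None:
        if not self.b0 > 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if self.theta < 0:
            raise ValueError(f"theta must be non-negative, got {self.theta}")
        if not (isinstance(self.C0, (int, np.integer)) and self.C0 >= 1):
            raise ValueError(f"C0 must be a positive integer, got {self.C0}")

    @property
    def gamma(self) -> float:
        """Recruitment-to-proliferation ratio θ·C0/b0 (dimensionless).

        Controls the rank-size exponent of the formed repertoire,
        α = 1 + γ, and the clonal turnover timescale.
        """
        return self.theta * self.C0 / self.b0


@dataclass(frozen=True)
class FluctParams:
    """Parameters of the fluctuating clonal growth-rate (Langevin) model.

    The log clone size x = log(C/C0) performs a Brownian motion with drift
    ``f0`` and variance growing as ``2·sigma2·t`` (geometric Brownian motion
    for C).  A negative drift balances ongoing recruitment of new clones.
    """

    f0: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be non-negative, got {self.sigma2}")
        # Requiring the expected linear-scale growth factor e^{f0+sigma2} of
        # existing clones not to exceed one gives -f0 >= sigma2 (alpha >= 1);
        # below that large clones deterministically expand their repertoire
        # share, which is not a sustainable steady hierarchy.
        if self.sigma2 > 0 and -self.f0 < self.sigma2:
            warnings.warn(
                "f0 + sigma2 > 0: mean clone size grows; large clones will "
                "deterministically take over (tail exponent alpha < 1)",
                stacklevel=2,
            )

    @property
    def alpha(self) -> float:
        """Steady-state rank-size exponent −f0/σ²."""
        if self.sigma2 == 0:
            raise ValueError("alpha undefined for sigma2=0")
        return -self.f0 / self.sigma2

    def tau(self, T: float) -> float:
        """Effective (rescaled) age τ = T·σ²."""
        return T * self.sigma2


@dataclass(frozen=True)
class CytokineParams:
    """Production/degradation/consumption rates of a shared proliferation
    stimulus (e.g. IL-7 class cytokines), motivating the 1/N competition."""

    p: float
    q: float
    k: float

    def __post_init__(self) -> None:
        for name in ("p", "q", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RelaxationParams:
    """Parameters of the zero-insertion relaxation sigmoid.

    ``r_star`` is the rank scale separating early-founded clones (perinatal,
    TdT-negative recombination with probability ``p0_minus`` of zero inserted
    nucleotides) from later clones (adult statistics, ``p0_plus``), and
    ``tau_d`` the diffusive timescale over which fluctuating selection
    reorders the clone-size hierarchy.
    """

    r_star: float
    tau_d: float
    p0_minus: float
    p0_plus: float

    def __post_init__(self) -> None:
        if not self.r_star >= 1:
            raise ValueError(f"r_star must be >= 1, got {self.r_star}")
        if not self.tau_d > 0:
            raise ValueError(f"tau_d must be positive, got {self.tau_d}")
        if not 0 <= self.p0_plus <= self.p0_minus <= 1:
            raise ValueError(
                "need 0 <= p0_plus <= p0_minus <= 1, got "
                f"p0_plus={self.p0_plus}, p0_minus={self.p0_minus}"
            )

    @property
    def delta_p0(self) -> float:
        return self.p0_minus - self.p0_plus

    def x_min(self, alpha: float, n_clones: float) -> float:
        """Log-size threshold equivalent of ``r_star`` under rank ≈ M·e^{−αx}."""
        return np.log(n_clones / self.r_star) / alpha


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cross-sectional cohort.

    Defaults are the simulated-cohort values used throughout: fluctuation
    strength σ²=0.08/year, death rate d=0.2/year, recruitment-to-
    proliferation ratio γ=0.1, recruitment rate θ=1e5 clones/year,
    zero-insertion probability 0.07 before the TdT switch at t†=0.05 years
    and 0.02 in the adult naive pool, 5e5 sampled reads per individual,
    ages uniform on [0, 80] years.
    """

    sigma2: float = 0.08
    d: float = 0.2
    gamma: float = 0.1
    theta: float = 1e5
    p0_minus: float = 0.07
    p0_plus: float = 0.02
    t_dagger: float = 0.05
    n_sample: float = 5e5
    age_range: tuple[float, float] = (0.0, 80.0)

    def __post_init__(self) -> None:
        for name in ("sigma2", "d", "gamma", "theta", "t_dagger", "n_sample"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.p0_plus <= self.p0_minus <= 1:
            raise ValueError("need 0 <= p0_plus <= p0_minus <= 1")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid age_range {self.age_range}")

    @property
    def fluct(self) -> FluctParams:
        """Equivalent Langevin parameters with drift set to −(1+γ)·σ²."""
        return FluctParams(f0=-(1.0 + self.gamma) * self.sigma2, sigma2=self.sigma2)


@dataclass
class CloneRecord:
    """One clonal lineage: when it was recruited, how big it is now, and
    whether its receptor has zero inserted nucleotides at both junctions."""

    id: int
    t_recruit: float
    size: float
    zero_insertions: bool = False

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if self.t_recruit < 0:
            raise ValueError("t_recruit must be >= 0")


@dataclass
class RepertoireSnapshot:
    """Clone sizes of one repertoire at a single observation time.

    Extinct clones (size 0) are excluded; ``n_extinct`` tallies them for
    diagnostics.  ``N`` always equals the sum of sizes.
    """

    time: float
    ids: np.ndarray
    t_recruit: np.ndarray
    sizes: np.ndarray
    zero_insertions: np.ndarray | None = None
    n_extinct: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.t_recruit = np.asarray(self.t_recruit, dtype=float)
        self.sizes = np.asarray(self.sizes)
        if np.any(self.sizes <= 0):
            raise ValueError("snapshots must not contain extinct clones")
        if self.zero_insertions is not None:
            self.zero_insertions = np.asarray(self.zero_insertions, dtype=bool)

    @property
    def N(self) -> float:
        return float(self.sizes.sum())

    @property
    def n_clones(self) -> int:
        return len(self.sizes)

    def __iter__(self) -> Iterator[CloneRecord]:
        zi = (
            self.zero_insertions
            if self.zero_insertions is not None
            else np.zeros(len(self.sizes), dtype=bool)
        )
        for i in range(len(self.sizes)):
            yield CloneRecord(
                id=int(self.ids[i]),
                t_recruit=float(self.t_recruit[i]),
                size=self.sizes[i].item(),
                zero_insertions=bool(zi[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "clone_id": self.ids,
                "count": self.sizes,
                "t_recruit": self.t_recruit,
            }
        )
        if self.zero_insertions is not None:
            df["zero_insertions"] = self.zero_insertions.astype(int)
        return df


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulator run."""

    params: FormationParams
    t_end: float
    record_times: tuple[float, ...]
    seed: int
    mode: str = "meanfield"

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        rts = tuple(float(t) for t in self.record_times)
        object.__setattr__(self, "record_times", rts)
        if not rts:
            raise ValueError("record_times must not be empty")
        if any(t < 0 or t > self.t_end for t in rts):
            raise ValueError("record_times must lie in [0, t_end]")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("record_times must be strictly increasing")
        if self.mode not in ("exact", "meanfield"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CloneSizeSample:
    """Sampled clone sizes (reads or UMIs) of one individual."""

    counts: np.ndarray
    age: float | None = None
    memory_fraction: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("counts must all be >= 1")
        if self.memory_fraction is not None and not 0 < self.memory_fraction <= 1:
            raise ValueError("memory_fraction must be in (0, 1]")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_clones(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class ExponentFit:
    """Result of the trimmed discrete power-law maximum-likelihood fit."""

    alpha_hat: float
    se: float
    c_min: int
    m_used: int
    at_bound: bool = False
    log_likelihood: float = np.nan


@dataclass
class CohortSample:
    """Sampled repertoire of one synthetic individual: read counts with
    aligned zero-insertion labels."""

    individual_id: int
    age: float
    counts: np.ndarray
    zero_insertions: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.zero_insertions = np.asarray(self.zero_insertions, dtype=bool)
        if self.counts.shape != self.zero_insertions.shape:
            raise ValueError("counts and zero_insertions must align")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("sampled counts must all be >= 1")

    @property
    def n_clones(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RelaxationFitResult:
    """Fitted sigmoid parameters with standard errors."""

    r_star: float
    r_star_se: float
    tau_d: float
    tau_d_se: float
    p0_minus: float
    p0_minus_se: float
    p0_plus: float
    p0_plus_se: float
    wrss: float
    n_points: int

    @property
    def params(self) -> RelaxationParams:
        return RelaxationParams(
            r_star=self.r_star,
            tau_d=self.tau_d,
            p0_minus=self.p0_minus,
            p0_plus=self.p0_plus,
        )

    def ci95(self, name: str) -> tuple[float, float]:
        """Normal-approximation 95% confidence interval for a parameter."""
        est = getattr(self, name)
        se = getattr(self, f"{name}_se")
        return (est - 1.96 * se, est + 1.96 * se)


@dataclass
class TrajectorySet:
    """Longitudinal clone-size observations: a clones x times count matrix.

    A count of zero means the clone was not detected in that sample.
    """

    clone_ids: np.ndarray
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.clone_ids = np.asarray(self.clone_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.counts.shape != (len(self.clone_ids), len(self.times)):
            raise ValueError(
                f"counts shape {self.counts.shape} incompatible with "
                f"{len(self.clone_ids)} clones x {len(self.times)} times"
            )
        if self.counts.min() < 0:
            raise ValueError("counts must be >= 0")

    @property
    def detected(self) -> np.ndarray:
        return self.counts > 0

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized by total reads per timepoint."""
        totals = self.counts.sum(axis=0).astype(float)
        if np.any(totals == 0):
            raise ValueError("timepoint with zero total reads")
        return self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        """Long-format (clone_id, time, count) table."""
        n, k = self.counts.shape
        return pd.DataFrame(
            {
                "clone_id": np.repeat(self.clone_ids, k),
                "time": np.tile(self.times, n),
                "count": self.counts.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySet":
        """Build from a long-format (clone_id, time, count) table; missing
        (clone, time) pairs become zero counts."""
        wide = df.pivot_table(
            index="clone_id", columns="time", values="count", fill_value=0
        ).sort_index(axis=1)
        return cls(
            clone_ids=wide.index.to_numpy(),
            times=wide.columns.to_numpy(dtype=float),
            counts=wide.to_numpy(),
        )


@dataclass(frozen=True)
class FluctuationEstimate:
    """Growth-rate fluctuation strength from the log-foldchange variance
    regression: slope/2 estimates σ², intercept/2 the sampling variance."""

    sigma2_hat: float
    sampling_var_hat: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    clipped: bool = False
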