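"""Stochastic simulation of repertoire formation and fluctuating selection.

Three simulators are provided:

* :func:`simulate_exact` — Gillespie simulation of the coupled
  birth-death-immigration system in which every cell of clone i proliferates
  at the shared competitive rate ``b0/N`` and dies at rate ``d``, and new
  clones of size ``C0`` immigrate at rate ``theta``.  All clones interact
  through the total size N, so events are drawn globally; clones are picked
  proportionally to their size via a Fenwick (binary indexed) tree.

* :func:`simulate_meanfield` — the mean-field competition approximation:
  the shared N in the per-cell birth rate is replaced by its deterministic
  average N̄(t) (:func:`tcrdyn.theory.mean_total_size`), which decouples the
  clones while retaining full demographic stochasticity per clone.  Each
  clone is an independent birth-death process with a time-dependent birth
  rate, simulated by thinning an inhomogeneous Poisson process: because the
  birth rate only decreases, the total event rate evaluated at the previous
  event time is a valid majorant, and proposed inter-event times drawn from
  it are accepted with probability rate(now)/majorant.

* :func:`simulate_fluctuating` — geometric Brownian motion of log clone
  sizes under growth-rate fluctuations (Euler increments, which are exact
  for this linear stochastic differential equation at any step size).

Reproducibility: one root seed; mean-field clones draw from per-clone child
streams derived by counter-based spawning so results do not depend on the
order in which clones are simulated.
"""

from __future__ import annotations

import math
import random as _pyrandom
from bisect import bisect_left

import numpy as np

from .theory import mean_total_size
from .types import FluctParams, RepertoireSnapshot, SimConfig

__all__ = ["simulate_exact", "simulate_meanfield", "simulate_fluctuating"]


class _Fenwick:
    """Fenwick tree over clone sizes: O(log M) update, prefix-sum search."""

    def __init__(self, capacity: int = 1024):
        self._n = capacity
        self._tree = [0] * (capacity + 1)
        self._size = 0  # number of leaves in use
        self.total = 0

    def append(self, value: int) -> int:
        if self._size == self._n:
            self._grow()
        i = self._size
        self._size += 1
        self.add(i, value)
        return i

    def _grow(self) -> None:
        values = [self.prefix(i + 1) - self.prefix(i) for i in range(self._size)]
        self._n *= 2
        self._tree = [0] * (self._n + 1)
        self.total = 0
        self._size = 0
        for v in values:
            self.append(v)

    def add(self, i: int, delta: int) -> None:
        self.total += delta
        i += 1
        tree = self._tree
        while i <= self._n:
            tree[i] += delta
            i += i & (-i)

    def prefix(self, i: int) -> int:
        s = 0
        tree = self._tree
        while i > 0:
            s += tree[i]
            i -= i & (-i)
        return s

    def find(self, value: float) -> int:
        """Smallest index i such that prefix_sum(i+1) > value."""
        idx = 0
        bit = 1 << (self._n.bit_length() - 1)
        tree = self._tree
        while bit:
            nxt = idx + bit
            if nxt <= self._n and tree[nxt] <= value:
                idx = nxt
                value -= tree[nxt]
            bit >>= 1
        return idx


def _make_snapshot(time, sizes, t_recruit, n_recruited):
    sizes = np.asarray(sizes)
    t_recruit = np.asarray(t_recruit, dtype=float)
    alive = sizes > 0
    return RepertoireSnapshot(
        time=float(time),
        ids=np.nonzero(alive)[0],
        t_recruit=t_recruit[alive],
        sizes=sizes[alive],
        n_extinct=int(n_recruited - alive.sum()),
    )


def simulate_exact(config: SimConfig, initial_clones=()) -> list[RepertoireSnapshot]:
    """Gillespie simulation of the full coupled formation model.

    The repertoire starts empty unless ``initial_clones`` seeds it with
    clone sizes at t=0.  Total event rate is ``theta + b0*1{N>0} + d*N``;
    per event N changes by +C0 (recruitment), +1 (proliferation) or -1
    (death).  Snapshots hold the state at the last event time at or before
    each requested record time.
    """
    if config.mode != "exact":
        raise ValueError(f"config.mode must be 'exact', got {config.mode!r}")
    p = config.params
    rng = np.random.default_rng(config.seed)
    fen = _Fenwick()
    sizes: list[int] = []
    t_recruit: list[float] = []
    for c in initial_clones:
        if not c >= 1:
            raise ValueError("initial clone sizes must be >= 1")
        fen.append(int(c))
        sizes.append(int(c))
        t_recruit.append(0.0)
    record_times = list(config.record_times)
    snapshots: list[RepertoireSnapshot] = []
    t = 0.0
    k = 0
    while True:
        N = fen.total
        lam = p.theta + (p.b0 if N > 0 else 0.0) + p.d * N
        t_new = t + rng.exponential(1.0 / lam) if lam > 0 else math.inf
        while k < len(record_times) and record_times[k] < t_new:
            snapshots.append(
                _make_snapshot(record_times[k], sizes, t_recruit, len(sizes))
            )
            k += 1
        if k == len(record_times) or t_new > config.t_end:
            break
        t = t_new
        u = rng.random() * lam
        if u < p.theta:
            fen.append(p.C0)
            sizes.append(p.C0)
            t_recruit.append(t)
        else:
            i = fen.find(rng.random() * N)
            if u < p.theta + p.b0:
                fen.add(i, 1)
                sizes[i] += 1
            else:
                fen.add(i, -1)
                sizes[i] -= 1
    return snapshots


def _child_seed(root_seed: int, stream: tuple[int, ...]) -> int:
    """Deterministic 64-bit child seed from a root seed and a stream key."""
    return int(
        np.random.SeedSequence(entropy=root_seed, spawn_key=stream).generate_state(1)[0]
    )


def _simulate_clone_meanfield(
    ti: float,
    C0: int,
    b0: float,
    d: float,
    rate0: float,
    t_end: float,
    record_times: list[float],
    rnd: _pyrandom.Random,
    out: np.ndarray,
) -> None:
    """Birth-death trajectory of one clone with per-cell birth rate
    b0/N̄(t); writes the clone's size at each record time into ``out``."""
    # N̄(t) = rate0 * (1 - e^{-d t}) / d  with rate0 = b0 + theta*C0
    t = ti
    C = C0
    K = len(record_times)
    k = bisect_left(record_times, ti)
    expovariate = rnd.expovariate
    uniform = rnd.random
    while True:
        nbar = rate0 * -math.expm1(-d * t) / d
        b_prev = b0 / nbar
        lam_star = C * (b_prev + d)  # majorant: rates only decrease
        t_new = t + expovariate(lam_star)
        while k < K and record_times[k] < t_new:
            out[k] = C
            k += 1
        if k == K or t_new > t_end:
            return
        t = t_new
        nbar = rate0 * -math.expm1(-d * t) / d
        b_now = b0 / nbar
        lam = C * (b_now + d)
        if uniform() * lam_star <= lam:  # thinning acceptance
            if uniform() * (b_now + d) < b_now:
                C += 1
            else:
                C -= 1
                if C == 0:
                    return  # extinct; remaining record times stay at 0


def simulate_meanfield(config: SimConfig) -> list[RepertoireSnapshot]:
    """Mean-field simulation: independent clones against the deterministic
    total size N̄(t), recruited by a homogeneous Poisson process of rate θ.

    Recruitment times are strictly positive almost surely (a clone at t=0
    exactly would face an infinite per-cell birth rate since N̄(0)=0).
    """
    if config.mode != "meanfield":
        raise ValueError(f"config.mode must be 'meanfield', got {config.mode!r}")
    p = config.params
    rate0 = p.b0 + p.theta * p.C0
    record_times = list(config.record_times)
    rng_recruit = np.random.default_rng(_child_seed(config.seed, (0,)))
    if p.theta > 0:
        # homogeneous Poisson arrivals on (0, t_end]
        n_exp = int(
            p.theta * config.t_end + 6 * math.sqrt(p.theta * config.t_end) + 10
        )
        arrivals = np.cumsum(rng_recruit.exponential(1.0 / p.theta, size=n_exp))
        while arrivals[-1] <= config.t_end:  # pragma: no cover - extreme tail
            extra = np.cumsum(rng_recruit.exponential(1.0 / p.theta, size=n_exp))
            arrivals = np.concatenate([arrivals, arrivals[-1] + extra])
        t_rec = arrivals[arrivals <= config.t_end]
    else:
        t_rec = np.empty(0)
    if np.any(t_rec <= 0):
        raise RuntimeError("recruitment time <= 0 should be impossible")
    n_clones = len(t_rec)
    sizes_at = np.zeros((len(record_times), n_clones), dtype=np.int64)
    child_entropy = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1,)
    ).generate_state(max(n_clones, 1), dtype=np.uint64)
    for i in range(n_clones):
        rnd = _pyrandom.Random(int(child_entropy[i]))
        _simulate_clone_meanfield(
            float(t_rec[i]),
            p.C0,
            p.b0,
            p.d,
            rate0,
            config.t_end,
            record_times,
            rnd,
            sizes_at[:, i],
        )
    snapshots = []
    for k, rt in enumerate(record_times):
        recruited = int(np.searchsorted(t_rec, rt, side="right"))
        sizes = sizes_at[k]
        alive = sizes > 0
        snapshots.append(
            RepertoireSnapshot(
                time=rt,
                ids=np.nonzero(alive)[0],
                t_recruit=t_rec[alive],
                sizes=sizes[alive],
                n_extinct=int(recruited - alive.sum()),
            )
        )
    return snapshots


def simulate_fluctuating(
    params: FluctParams,
    x0,
    dt_grid,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Log clone-size trajectories under fluctuating net growth rates.

    ``x(t+dt) = x(t) + f0*dt + sqrt(2*sigma2*dt) * z`` with standard normal
    z — the exact transition of the linear SDE at any step.  Returns an
    array of shape ``(n_clones, len(dt_grid))`` whose first column is
    ``x0`` at time ``dt_grid[0]``.
    """
    times = np.asarray(dt_grid, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("dt_grid must be a 1-D time grid")
    if np.any(np.diff(times) <= 0):
        raise ValueError("dt_grid must be strictly increasing")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n = len(x0)
    dts = np.diff(times)
    x = np.empty((n, len(times)))
    x[:, 0] = x0
    if len(dts):
        incs = params.f0 * dts + np.sqrt(
            2.0 * params.sigma2 * dts
        ) * rng.standard_normal((n, len(dts)))
        x[:, 1:] = x0[:, None] + np.cumsum(incs, axis=1)
    return x
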