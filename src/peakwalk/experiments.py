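"""Headline search experiments: parallel searches, regeneration, multi-peak.

Three questions about escaping the exponential barrier:

* **Parallel independent searches.**  With per-search success probability p
  within a budget, an ensemble of t independent searches succeeds with
  probability 1 - (1 - p)**t.  When p is exponentially small in L, no
  polynomial number of searches rescues the ensemble —
  :func:`parallel_experiment` demonstrates the product law empirically
  against the exact dynamic-programming value.

* **Regeneration.**  If some process (gene duplication, rearrangement) keeps
  producing fresh starting sequences a *constant* number k0 of mutations from
  the target, each budgeted attempt succeeds with probability ~ L**(-k0)
  (polynomially small, not exponentially small), so ~ 3/p attempts give a
  95% ensemble success with polynomially many searches of polynomial length.
  :func:`regeneration_experiment` measures the per-attempt success across an
  L-grid and fits its power law.

* **Uniformly random multi-peak landscapes.**  For m random target centers
  of radius w, the neutral walk mixes fast and spends a uniform fraction of
  its time in the target, so the expected discovery time is of order
  A**L / (m * ball_volume(L, w, A)) — :func:`stationary_time_estimate` —
  which :func:`multi_target_experiment` checks by simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Sequence

import numpy as np
from scipy.stats import linregress

from .chain import BirthDeathChain, neutral_chain
from .hitting import success_within
from .landscapes import MultiPeakLandscape
from .sequences import SequenceSpace, ball_volume
from .simulate import (
    ExperimentSummary,
    simulate_projected_batch,
    simulate_space_batch,
    summarize_times,
)

__all__ = [
    "parallel_success",
    "parallel_experiment",
    "ParallelReport",
    "absorption_before",
    "regeneration_experiment",
    "RegenerationReport",
    "multi_target_experiment",
    "MultiTargetReport",
    "stationary_time_estimate",
    "StationaryEstimate",
    "DegenerateTargetError",
]


class DegenerateTargetError(ValueError):
    """Raised when the target set covers (almost) the whole space."""


def parallel_success(p_single: float, t: int) -> float:
    """Ensemble success probability of t independent searches.

    1 - (1 - p)**t, evaluated stably for tiny p via log1p/expm1 so that
    p = 1e-12, t = 1e6 comes out as ~ 1e-6 with full relative accuracy.
    """
    if not 0.0 <= p_single <= 1.0:
        raise ValueError(f"p_single={p_single} outside [0, 1]")
    if t < 1:
        raise ValueError("t must be >= 1")
    if p_single == 1.0:
        return 1.0
    return -math.expm1(t * math.log1p(-p_single))


@dataclass(frozen=True)
class ParallelReport:
    """Empirical vs exact ensemble success for parallel independent searches."""

    t: int
    T: int
    start: int
    n_meta: int
    p_single_exact: float
    p_ensemble_exact: float
    p_ensemble_empirical: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "T": self.T,
            "start": self.start,
            "n_meta": self.n_meta,
            "p_single_exact": self.p_single_exact,
            "p_ensemble_exact": self.p_ensemble_exact,
            "p_ensemble_empirical": self.p_ensemble_empirical,
            "seed": self.seed,
        }


def parallel_experiment(
    chain: BirthDeathChain,
    start: int,
    t: int,
    T: int,
    n_meta: int,
    seed: int,
) -> ParallelReport:
    """Simulate ``n_meta`` replicates of t parallel searches of budget T each.

    Each replicate succeeds when any of its t searches reaches the target;
    the empirical ensemble frequency is reported next to the exact value
    1 - (1 - p)**t with p from finite-horizon dynamic programming.
    """
    if t < 1 or n_meta < 1:
        raise ValueError("t and n_meta must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    times = simulate_projected_batch(chain, start, T, n_meta * t, rng)
    ensemble_hit = (times.reshape(n_meta, t) >= 0).any(axis=1)
    p = success_within(chain, start, T)
    return ParallelReport(
        t=t,
        T=T,
        start=start,
        n_meta=n_meta,
        p_single_exact=p,
        p_ensemble_exact=parallel_success(p, t),
        p_ensemble_empirical=float(ensemble_hit.mean()),
        seed=seed,
    )


def absorption_before(
    chain: BirthDeathChain, start: int, low: int, high: int
) -> float:
    """Probability the chain reaches state ``low`` before state ``high``.

    Gambler's-ruin closed form on the embedded jump chain: with
    r_i = p_up[i]/p_down[i] for interior states, the probability of reaching
    ``high`` before ``low`` from k is the ratio of partial sums of the
    products prod_{i=low+1..j} (p_down[i]/p_up[i])... computed here in the
    standard telescoping form.  Self-loops cancel and do not affect the
    answer.
    """
    if not low < start < high:
        if start == low:
            return 1.0
        if start == high:
            return 0.0
        raise ValueError(f"need low <= start <= high, got {low}, {start}, {high}")
    if not (0 <= low and high <= chain.L):
        raise ValueError("boundaries outside chain state range")
    # h(k) = P(hit high before low); h = S_{k-low}/S_{high-low} with
    # S_j = sum_{i=0..j-1} prod_{l=1..i} (p_down[low+l]/p_up[low+l])
    terms = np.empty(high - low, dtype=float)
    terms[0] = 1.0
    prod = 1.0
    for i in range(1, high - low):
        s = low + i
        if chain.p_up[s] <= 0:
            # upward motion impossible: high never reached from here
            prod = np.inf
        else:
            prod *= chain.p_down[s] / chain.p_up[s]
        terms[i] = prod
    csum = np.cumsum(terms)
    h_high = csum[start - low - 1] / csum[-1] if np.isfinite(csum[-1]) else 0.0
    return float(1.0 - h_high)


@dataclass(frozen=True)
class RegenerationReport:
    """Per-attempt success of budgeted searches started k0 steps from target."""

    k0: int
    A: int
    w: int
    L_grid: np.ndarray
    budgets: np.ndarray
    n_attempts: int
    p_hat: np.ndarray  # per-attempt empirical success per L
    p_exact: np.ndarray  # finite-horizon DP value per L
    n_for_95: np.ndarray  # ceil(3 / p_hat): attempts for >= 95% ensemble success
    slope: float  # fitted d log p_hat / d log L  (nan when grid has < 2 lengths)
    slope_r2: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "k0": self.k0,
            "A": self.A,
            "w": self.w,
            "L_grid": self.L_grid.tolist(),
            "budgets": self.budgets.tolist(),
            "n_attempts": self.n_attempts,
            "p_hat": self.p_hat.tolist(),
            "p_exact": self.p_exact.tolist(),
            "n_for_95": self.n_for_95.tolist(),
            "slope": self.slope,
            "slope_r2": self.slope_r2,
            "seed": self.seed,
        }


def regeneration_experiment(
    L_grid: Sequence[int] | int,
    A: int,
    k0: int,
    n_attempts: int,
    seed: int,
    w: int = 0,
    budget_factor: float = 20.0,
) -> RegenerationReport:
    """Budgeted searches regenerated a constant k0 mutations from the target.

    For each L in the grid, ``n_attempts`` independent walks start at distance
    exactly k0 from the target center (width ``w``, default 0 — the hardest
    case) with a per-search budget ``budget_factor * L**2`` events.  The
    per-attempt success p_hat is polynomially small (~ L**-k0), so the report
    also carries ceil(3/p_hat), the number of regenerated attempts that makes
    the ensemble succeed with probability >= 1 - e**-3 ~ 0.95.

    Walks run on the projected chain, which is distributionally identical to
    the full-space walk on a broad-peak landscape.
    """
    L_values = [L_grid] if isinstance(L_grid, int) else sorted(L_grid)
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    for L in L_values:
        if not 0 <= w < L:
            raise ValueError(f"target width w={w} outside [0, L={L})")
        if not 0 <= k0 <= L - w:
            raise ValueError(f"k0={k0} must satisfy 0 <= k0 <= L - w for L={L}")
    ss = np.random.SeedSequence(seed).spawn(len(L_values))
    p_hat, p_exact, budgets = [], [], []
    for L, child in zip(L_values, ss):
        T = int(budget_factor * L * L)
        chain = neutral_chain(L, A, w)
        start = w + k0
        if k0 == 0:
            p_hat.append(1.0)
            p_exact.append(1.0)
            budgets.append(T)
            continue
        rng = np.random.default_rng(child)
        times = simulate_projected_batch(chain, start, T, n_attempts, rng)
        p_hat.append(float((times >= 0).mean()))
        p_exact.append(success_within(chain, start, T))
        budgets.append(T)
    p_hat = np.array(p_hat)
    p_exact = np.array(p_exact)
    if len(L_values) >= 2 and (p_hat > 0).all():
        fit = linregress(np.log(L_values), np.log(p_hat))
        slope, r2 = float(fit.slope), float(fit.rvalue**2)
    else:
        slope, r2 = float("nan"), float("nan")
    with np.errstate(divide="ignore"):
        n95 = np.where(p_hat > 0, np.ceil(3.0 / np.maximum(p_hat, 1e-300)), np.inf)
    return RegenerationReport(
        k0=k0,
        A=A,
        w=w,
        L_grid=np.array(L_values),
        budgets=np.array(budgets),
        n_attempts=n_attempts,
        p_hat=p_hat,
        p_exact=p_exact,
        n_for_95=n95,
        slope=slope,
        slope_r2=r2,
        seed=seed,
    )


@dataclass(frozen=True)
class StationaryEstimate:
    """Stationary-mass expected discovery time for uniform random targets.

    ``value`` is A**L / (m * ball_volume(L, w, A)) as an exact rational: the
    expected number of independent-uniform epochs before landing in the
    target, valid up to the (separately annotated) mixing-time polynomial
    factor of order L*log(L) events per epoch.
    """

    value: Fraction
    degenerate: bool
    mixing_scale: float  # O(L log L) annotation, not folded into value

    def __float__(self) -> float:
        return float(self.value)


def stationary_time_estimate(L: int, A: int, m: int, w: int) -> StationaryEstimate:
    """Expected epochs to hit one of m random radius-w targets under fast mixing."""
    if m < 1:
        raise ValueError("m must be >= 1")
    vol = ball_volume(L, w, A)
    total = A**L
    degenerate = m * vol >= total
    return StationaryEstimate(
        value=Fraction(total, m * vol),
        degenerate=degenerate,
        mixing_scale=L * math.log(max(L, 2)),
    )


@dataclass(frozen=True)
class MultiTargetReport:
    """Simulation of discovery on a uniformly random multi-peak landscape."""

    L: int
    A: int
    m: int
    w: int
    budget: int
    n_runs: int
    summary: ExperimentSummary
    stationary_estimate: float
    mixing_scale: float
    seed: int

    def to_dict(self) -> dict:
        d = self.summary.to_dict()
        d.update(
            {
                "L": self.L,
                "A": self.A,
                "m": self.m,
                "w": self.w,
                "stationary_estimate": self.stationary_estimate,
                "mixing_scale": self.mixing_scale,
            }
        )
        return d


def multi_target_experiment(
    L: int,
    A: int,
    m: int,
    w: int,
    budget: int,
    n_runs: int,
    seed: int,
    alphabet: str | None = None,
) -> MultiTargetReport:
    """Walks from random non-target starts toward m uniformly random targets.

    Target centers are drawn uniformly from the space; each run starts at a
    uniform random sequence outside the target (rejection sampling — the
    experiment refuses when targets cover more than half the space, a regime
    outside the stationary-mass theory).  Reports the mean discovery time and
    success probability next to the stationary-mass estimate
    A**L / (m * ball_volume).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    est = stationary_time_estimate(L, A, m, w)
    coverage = float(1 / est.value)  # m * ball_volume / A**L
    if coverage > 0.5:
        raise DegenerateTargetError(
            f"targets cover fraction {coverage:.3f} > 0.5 of the space"
        )
    alphabet = alphabet or ("ACGT" if A == 4 else "".join(chr(48 + i) for i in range(A)))
    space = SequenceSpace(L, alphabet[:A])
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_land = np.random.default_rng(ss[0])
    rng_walk = np.random.default_rng(ss[1])
    landscape = MultiPeakLandscape.random(space, m, w, rng_land)
    # rejection-sample non-target starts
    starts = np.empty((n_runs, L), dtype=np.int8)
    cen = np.stack([space.encode(c) for c in landscape.centers])
    filled = 0
    while filled < n_runs:
        cand = rng_walk.integers(0, A, size=(n_runs - filled, L)).astype(np.int8)
        dist = (cand[:, None, :] != cen[None, :, :]).sum(axis=2)
        ok = (dist > w).all(axis=1)
        k = int(ok.sum())
        starts[filled : filled + k] = cand[ok]
        filled += k
    times = simulate_space_batch(landscape, starts, budget, rng_walk)
    summary = summarize_times(times, budget, seed)
    return MultiTargetReport(
        L=L,
        A=A,
        m=m,
        w=w,
        budget=budget,
        n_runs=n_runs,
        summary=summary,
        stationary_estimate=float(est.value),
        mixing_scale=est.mixing_scale,
        seed=seed,
    )
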