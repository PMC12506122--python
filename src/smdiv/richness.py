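"""Incidence-based rarefaction, Chao2 richness estimation, and extrapolation.

Given a species × GCF presence/absence matrix with T sampling units and
observed richness S_obs, the classical sample-based machinery is:

* interpolation (rarefaction) — the exact hypergeometric expectation of
  richness in a random subset of t units,

      E[S(t)] = S_obs − Σ_i C(T − Y_i, t) / C(T, t),

  where Y_i is the number of units occupied by GCF i;

* undetected richness — the Chao2 estimator from the counts of uniques
  (Q1, GCFs in exactly one unit) and duplicates (Q2, exactly two),

      Q0_hat = ((T−1)/T) · Q1² / (2·Q2)          if Q2 > 0
      Q0_hat = ((T−1)/T) · Q1·(Q1−1) / 2          if Q2 = 0  (bias-corrected),

  with S_est = S_obs + Q0_hat;

* extrapolation to T + t* units,

      S(T + t*) = S_obs + Q0_hat · [1 − (1 − Q1/(Q1 + T·Q0_hat))^t*],

  which is continuous with rarefaction at t* = 0 and approaches the
  asymptote S_obs + Q0_hat.

Confidence intervals come from a percentile bootstrap over sampling units:
units are resampled with replacement, the full curve is recomputed per
replicate, and 2.5/97.5 percentiles are taken pointwise.

Binomial coefficients are evaluated as log-gamma differences, since values
such as C(135, 60) overflow any direct path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .incidence import IncidenceMatrix

__all__ = [
    "IncidenceFrequencies",
    "RichnessEstimate",
    "RarefactionCurve",
    "frequencies",
    "rarefy",
    "chao2",
    "extrapolate",
    "curve",
    "richness_at",
]

Regime = Literal["interpolated", "observed", "extrapolated"]


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Per-GCF occupancy counts with their Chao2 sufficient statistics."""

    T: int
    Y: np.ndarray  # occupancy of each observed GCF, each in 1..T

    def __post_init__(self) -> None:
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=np.int64))
        if self.Y.size < 1:
            raise ValueError("need at least one observed GCF")
        if self.Y.min() < 1 or self.Y.max() > self.T:
            raise ValueError("occupancies must lie in 1..T")

    @property
    def S_obs(self) -> int:
        return int(self.Y.size)

    @property
    def Q1(self) -> int:
        return int((self.Y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Y == 2).sum())


@dataclass(frozen=True)
class RichnessEstimate:
    S_obs: int
    Q0_hat: float
    S_est: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class CurvePoint:
    t: int
    richness: float
    ci_low: float
    ci_high: float
    regime: Regime


@dataclass(frozen=True)
class RarefactionCurve:
    points: tuple[CurvePoint, ...]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([vars(p) for p in self.points])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def frequencies(matrix: IncidenceMatrix) -> IncidenceFrequencies:
    """Collapse an incidence matrix to its occupancy-count representation."""
    return IncidenceFrequencies(T=matrix.n_units, Y=matrix.cells.sum(axis=0))


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(freqs: IncidenceFrequencies, t: int) -> float:
    """Expected richness in a random subset of ``t`` of the T units (exact)."""
    T, Y = freqs.T, freqs.Y
    if not 1 <= t <= T:
        raise ValueError(f"t must lie in 1..{T}, got {t}")
    if t == T:
        return float(freqs.S_obs)
    # P(GCF i absent from the subset) = C(T - Y_i, t) / C(T, t); zero when T - Y_i < t
    absent = Y[Y <= T - t]
    if absent.size == 0:
        return float(freqs.S_obs)
    log_p = _log_choose(T - absent.astype(float), float(t)) - _log_choose(float(T), float(t))
    return float(freqs.S_obs - np.exp(log_p).sum())


def chao2(freqs: IncidenceFrequencies) -> RichnessEstimate:
    """Chao2 lower-bound-type estimate of total richness, with the (T−1)/T
    small-sample correction and the bias-corrected branch when Q2 = 0."""
    T = freqs.T
    if T < 2:
        raise ValueError("Chao2 requires at least two sampling units")
    Q1, Q2 = freqs.Q1, freqs.Q2
    k = (T - 1) / T
    Q0 = k * Q1 * Q1 / (2.0 * Q2) if Q2 > 0 else k * Q1 * (Q1 - 1) / 2.0
    return RichnessEstimate(S_obs=freqs.S_obs, Q0_hat=Q0, S_est=freqs.S_obs + Q0)


def extrapolate(freqs: IncidenceFrequencies, t_star: float) -> float:
    """Expected richness at T + t_star units (t_star ≥ 0).

    Flat at S_obs when there are no uniques (Q1 = 0): with no singletons the
    estimated undetected richness is zero and the curve has saturated.
    """
    if t_star < 0:
        raise ValueError("t_star must be non-negative")
    if t_star == 0:
        return float(freqs.S_obs)
    Q1 = freqs.Q1
    if Q1 == 0:
        return float(freqs.S_obs)
    Q0 = chao2(freqs).Q0_hat
    if Q0 == 0.0:  # Q1 == 1 with Q2 == 0 gives Q0 = 0
        return float(freqs.S_obs)
    frac = Q1 / (Q1 + freqs.T * Q0)
    return float(freqs.S_obs + Q0 * (1.0 - (1.0 - frac) ** t_star))


def _curve_values(freqs: IncidenceFrequencies, t_grid: Sequence[int]) -> np.ndarray:
    return np.array([rarefy(freqs, t) if t <= freqs.T else extrapolate(freqs, t - freqs.T)
                     for t in t_grid])


def curve(
    matrix: IncidenceMatrix,
    t_grid: Sequence[int],
    n_boot: int = 200,
    seed: int | None = None,
    ci: float = 0.95,
) -> RarefactionCurve:
    """Rarefaction/extrapolation curve with percentile-bootstrap CIs.

    Point estimates come from the observed occupancy frequencies; the CI at
    each grid point is the percentile interval over ``n_boot`` replicates in
    which the T sampling units are resampled with replacement and the whole
    curve recomputed.  Identical ``seed`` gives identical output.
    """
    t_grid = list(t_grid)
    if t_grid != sorted(t_grid) or (t_grid and t_grid[0] < 1):
        raise ValueError("t_grid must be sorted and positive")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    freqs = frequencies(matrix)
    est = _curve_values(freqs, t_grid)

    rng = np.random.default_rng(seed)
    T = matrix.n_units
    boots = np.empty((n_boot, len(t_grid)))
    for b in range(n_boot):
        idx = rng.integers(0, T, size=T)
        cells = matrix.cells[idx]
        occ = cells.sum(axis=0)
        bf = IncidenceFrequencies(T=T, Y=occ[occ > 0])
        boots[b] = _curve_values(bf, t_grid)
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)

    points = []
    for t, r, l, h in zip(t_grid, est, lo, hi):
        regime: Regime = ("observed" if t == T else
                          "interpolated" if t < T else "extrapolated")
        points.append(CurvePoint(t=int(t), richness=float(r),
                                 ci_low=float(l), ci_high=float(h), regime=regime))
    return RarefactionCurve(points=tuple(points))


def richness_at(
    matrix: IncidenceMatrix,
    n_target: int,
    n_boot: int = 200,
    seed: int | None = None,
    ci: float = 0.95,
) -> RichnessEstimate:
    """Extrapolated richness at ``n_target`` (≥ T) sampling units, with a
    percentile-bootstrap CI and standard error."""
    freqs = frequencies(matrix)
    T = freqs.T
    if n_target < T:
        raise ValueError(f"n_target ({n_target}) < T ({T}); use rarefy for interpolation")
    est = extrapolate(freqs, n_target - T)
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, T, size=T)
        occ = matrix.cells[idx].sum(axis=0)
        bf = IncidenceFrequencies(T=T, Y=occ[occ > 0])
        reps[b] = extrapolate(bf, n_target - T)
    alpha = (1.0 - ci) / 2.0
    q0 = chao2(freqs).Q0_hat
    return RichnessEstimate(
        S_obs=freqs.S_obs, Q0_hat=q0, S_est=est,
        se=float(reps.std(ddof=1)) if n_boot > 1 else 0.0,
        # clamp so the interval always brackets the point estimate (percentile
        # intervals can miss it under resampling bias at small n_boot)
        ci_low=min(float(np.quantile(reps, alpha)), est),
        ci_high=max(float(np.quantile(reps, 1.0 - alpha)), est),
    )
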