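"""Automatic threshold selection on gray-level histograms.

Two classic selectors are provided, both operating purely on the histogram
probabilities ``p_i``:

* **Maximum entropy** (Kapur-style): a threshold ``t`` splits the levels
  into background ``C0 = {0..t}`` and foreground ``C1 = {t+1..L-1}``; the
  selected ``t*`` maximises the sum of the Shannon entropies of the two
  normalised class distributions,

  ``f(t) = H0(t) + H1(t)``,
  ``H0 = -sum_{i<=t} (p_i/w0) log(p_i/w0)``, analogously for ``H1``.

* **Minimum classification error** (Kittler-Illingworth-style): assuming
  each class is Gaussian, ``t*`` minimises

  ``J(t) = 1 + w0 log(s0^2 / w0^2) + w1 log(s1^2 / w1^2)``,

  where ``w``, ``m``, ``s^2`` are the class probabilities, means and
  variances at ``t``.  The additive constant does not move the argmin.

Conventions fixed across the package: natural logarithms; ``0 log 0 = 0``;
ties in the arg-extremum broken toward the smallest ``t``; candidate
thresholds range over ``{min nonzero level, ..., max nonzero level - 1}``
so that both classes are always non-empty; candidates whose class variance
vanishes are invalid for the minimum-error objective (the log diverges) and
are excluded rather than floored.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyClassError, NoValidThresholdError
from .image import GrayHistogram

__all__ = [
    "ThresholdClassStats",
    "ThresholdScan",
    "class_stats",
    "entropy_sum",
    "max_entropy_threshold",
    "min_error_threshold",
]


@dataclass(frozen=True)
class ThresholdClassStats:
    """All per-threshold class quantities at a candidate threshold ``t``.

    ``C0`` collects gray levels ``<= t``, ``C1`` levels ``> t``.  For an
    empty class the mean, variance and entropy are NaN (undefined), never
    silently zero; check :attr:`c0_empty` / :attr:`c1_empty`.
    """

    t: int
    w0: float
    w1: float
    m0: float
    m1: float
    s0sq: float
    s1sq: float
    H0: float
    H1: float

    @property
    def c0_empty(self) -> bool:
        return self.w0 == 0.0

    @property
    def c1_empty(self) -> bool:
        return self.w1 == 0.0


@dataclass(frozen=True)
class ThresholdScan:
    """Objective trace of a threshold selector over all candidate ``t``.

    ``candidates[k]`` is a threshold value, ``objective[k]`` the objective
    there (NaN where the candidate is invalid), ``valid[k]`` whether it
    entered the arg-extremum, and ``t_star`` the selected threshold.
    """

    candidates: np.ndarray
    objective: np.ndarray
    valid: np.ndarray
    t_star: int
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("max_entropy", "min_error"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.t_star not in self.candidates[self.valid]:
            raise ValueError("t_star must be a valid candidate")

    @property
    def objective_at_star(self) -> float:
        k = int(np.flatnonzero(self.candidates == self.t_star)[0])
        return float(self.objective[k])

    def to_csv(self, path: str | Path) -> None:
        """Export the scan as CSV with columns ``t, objective, valid``."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "objective", "valid"])
            for t, obj, ok in zip(self.candidates, self.objective, self.valid):
                writer.writerow([int(t), repr(float(obj)), int(bool(ok))])


def _entropy(p: np.ndarray, w: float) -> float:
    """Shannon entropy (nats) of the class distribution p_i / w; 0 log 0 = 0."""
    q = p[p > 0] / w
    return float(-np.sum(q * np.log(q)))


def class_stats(hist: GrayHistogram, t: int) -> ThresholdClassStats:
    """Class probabilities, means, variances and entropies at threshold ``t``.

    Requires ``0 <= t <= L - 2``.  Undefined quantities of an empty class
    come back as NaN.
    """
    L = hist.levels
    if not 0 <= t <= L - 2:
        raise ValueError(f"threshold t={t} outside [0, {L - 2}]")
    p = hist.probabilities
    levels = np.arange(L, dtype=np.float64)
    p0, p1 = p[: t + 1], p[t + 1 :]
    i0, i1 = levels[: t + 1], levels[t + 1 :]
    w0 = float(p0.sum())
    w1 = float(p1.sum())

    def moments(pk: np.ndarray, ik: np.ndarray, wk: float) -> tuple[float, float, float]:
        if wk == 0.0:
            return math.nan, math.nan, math.nan
        m = float((ik * pk).sum() / wk)
        ssq = float((pk * (ik - m) ** 2).sum() / wk)
        return m, ssq, _entropy(pk, wk)

    m0, s0sq, H0 = moments(p0, i0, w0)
    m1, s1sq, H1 = moments(p1, i1, w1)
    return ThresholdClassStats(
        t=t, w0=w0, w1=w1, m0=m0, m1=m1, s0sq=s0sq, s1sq=s1sq, H0=H0, H1=H1
    )


def entropy_sum(hist: GrayHistogram, t: int) -> float:
    """Entropy objective ``f(t) = H0 + H1`` at threshold ``t``.

    Raises :class:`EmptyClassError` if either class has zero probability.
    """
    stats = class_stats(hist, t)
    if stats.c0_empty or stats.c1_empty:
        raise EmptyClassError(f"t={t} leaves an empty class; f(t) undefined")
    return stats.H0 + stats.H1


def _candidate_range(hist: GrayHistogram) -> np.ndarray:
    nz = hist.nonzero_levels
    if nz.size < 2:
        raise NoValidThresholdError(
            "histogram has mass on fewer than two gray levels; no threshold "
            "separates two non-empty classes"
        )
    return np.arange(nz[0], nz[-1])  # t in [lo, hi-1]: both classes non-empty


def _cumulative_stats(hist: GrayHistogram, cand: np.ndarray):
    """Vectorised w/m/s^2 and entropy ingredients for every candidate t.

    Class moments are accumulated in integer arithmetic (exact for any
    realistic pixel count), so a point-mass class yields variance exactly
    zero and is excluded from the minimum-error objective reliably rather
    than surviving as a catastrophically cancelled epsilon.
    """
    c = hist.counts
    n = hist.total
    i = np.arange(hist.levels, dtype=np.int64)
    C0 = np.cumsum(c)[cand]
    M0 = np.cumsum(i * c)[cand]
    V0 = np.cumsum(i * i * c)[cand]
    C1 = n - C0
    M1 = int((i * c).sum()) - M0
    V1 = int((i * i * c).sum()) - V0

    w0 = C0 / n
    w1 = C1 / n
    m0 = M0 / C0  # candidate range guarantees C0, C1 >= 1
    m1 = M1 / C1
    s0sq = (V0 * C0 - M0**2) / C0.astype(np.float64) ** 2  # exact int numerator
    s1sq = (V1 * C1 - M1**2) / C1.astype(np.float64) ** 2

    p = hist.probabilities
    with np.errstate(divide="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cs0 = np.cumsum(plogp)[cand]
    return w0, w1, m0, m1, s0sq, s1sq, cs0, plogp.sum()


def max_entropy_threshold(hist: GrayHistogram) -> ThresholdScan:
    """Select the threshold maximising the two-class entropy sum ``f(t)``.

    The full objective trace over the candidate range is retained in the
    returned :class:`ThresholdScan`; ties break to the smallest ``t``.
    """
    cand = _candidate_range(hist)
    w0, w1, _, _, _, _, cs0, s_all = _cumulative_stats(hist, cand)
    # H0 = log w0 - (sum_{i<=t} p log p) / w0 ; H1 analogous on the tail.
    H0 = np.log(w0) - cs0 / w0
    H1 = np.log(w1) - (s_all - cs0) / w1
    f = H0 + H1
    valid = np.isfinite(f)
    if not valid.any():
        raise NoValidThresholdError("entropy objective undefined at every candidate")
    best = np.nanmax(np.where(valid, f, -np.inf))
    t_star = int(cand[np.flatnonzero(valid & (f == best))[0]])
    obj = np.where(valid, f, np.nan)
    return ThresholdScan(
        candidates=cand, objective=obj, valid=valid, t_star=t_star, method="max_entropy"
    )


def min_error_threshold(hist: GrayHistogram) -> ThresholdScan:
    """Select the threshold minimising the Gaussian-mixture error objective.

    Candidates where either class is empty or has zero variance are
    excluded (the log term diverges there).  Raises
    :class:`NoValidThresholdError` when no candidate survives, e.g. for a
    two-point histogram where every class is a single spike.
    """
    cand = _candidate_range(hist)
    w0, w1, _, _, s0sq, s1sq, _, _ = _cumulative_stats(hist, cand)
    valid = (w0 > 0) & (w1 > 0) & (s0sq > 0) & (s1sq > 0)
    J = np.full(cand.shape, np.nan)
    if valid.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            J[valid] = (
                1.0
                + w0[valid] * np.log(s0sq[valid] / w0[valid] ** 2)
                + w1[valid] * np.log(s1sq[valid] / w1[valid] ** 2)
            )
        valid &= np.isfinite(J)
    if not valid.any():
        raise NoValidThresholdError(
            "minimum-error objective has no valid candidate (all class "
            "variances vanish); the histogram does not look two-Gaussian"
        )
    best = np.nanmin(np.where(valid, J, np.inf))
    t_star = int(cand[np.flatnonzero(valid & (J == best))[0]])
    return ThresholdScan(
        candidates=cand, objective=J, valid=valid, t_star=t_star, method="min_error"
    )
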