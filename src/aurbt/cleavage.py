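"""Bulk cleavage kinetics: mono-exponential fits and rate fold-changes.

A cleavage time course records the fraction of substrate cleaved at a
set of quench times.  Each replicate is fit independently to

    Y = A (1 - exp(-kobs t))

by bounded nonlinear least squares, and the apparent rate kobs (1/min)
is reported as mean +/- SD across replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class CleavageTimecourse:
    """Fraction cleaved versus time, one row per replicate."""

    times_min: np.ndarray
    fraction: np.ndarray  # shape (n_reps, n_times), values in [0, 1]
    replicate_ids: List[str] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.fraction = np.atleast_2d(np.asarray(self.fraction, dtype=float))
        if np.any(self.times_min < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fraction.shape[1] != self.times_min.size:
            raise ValueError("fraction rows must match the time grid")
        if np.any(self.fraction < 0) or np.any(self.fraction > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not self.replicate_ids:
            self.replicate_ids = [f"rep{i + 1}" for i in range(self.fraction.shape[0])]

    @property
    def n_reps(self) -> int:
        return self.fraction.shape[0]


@dataclass
class CleavageFit:
    """Per-replicate (A, kobs) fits and their mean +/- SD."""

    A: np.ndarray
    kobs: np.ndarray
    converged: np.ndarray
    A_mean: float
    kobs_mean: float
    A_sd: Optional[float]
    kobs_sd: Optional[float]
    flags: List[str] = field(default_factory=list)


def fraction_cleaved(band_intensities: Sequence[Dict[str, float]],
                     times_min: Sequence[float],
                     replicate_ids: Optional[List[str]] = None) -> CleavageTimecourse:
    """Gel quantification: fraction = cleaved product / total lane signal.

    ``band_intensities`` is one mapping per lane with a ``product`` key
    and either a ``total`` key or the remaining band intensities, which
    are summed together with the product to form the lane total.
    """
    fracs = []
    for lane in band_intensities:
        if "product" not in lane:
            raise ValueError("each lane needs a 'product' intensity")
        product = float(lane["product"])
        if product < 0 or any(float(v) < 0 for v in lane.values()):
            raise ValueError("band intensities must be non-negative")
        if "total" in lane:
            total = float(lane["total"])
        else:
            total = sum(float(v) for v in lane.values())
        if total <= 0:
            raise ValueError("total lane signal must be positive")
        fracs.append(product / total)
    times = np.asarray(times_min, dtype=float)
    arr = np.asarray(fracs, dtype=float).reshape(-1, times.size)
    return CleavageTimecourse(times_min=times, fraction=arr,
                              replicate_ids=replicate_ids or [])


def _monoexp(t, A, k):
    return A * (1.0 - np.exp(-k * t))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple:
    """A0 = max fraction; k0 = 1/t at half-max by log interpolation."""
    a0 = max(float(y.max()), 1e-3)
    half = 0.5 * a0
    above = np.nonzero(y >= half)[0]
    if above.size:
        t_half = max(float(t[above[0]]), float(t[t > 0].min()) if np.any(t > 0) else 1.0)
        k0 = math.log(2.0) / t_half
    else:
        k0 = 1.0 / max(float(t[-1]), 1.0)
    return a0, k0


def fit_monoexp(tc: CleavageTimecourse) -> CleavageFit:
    """Fit Y = A (1 - exp(-kobs t)) per replicate; report mean +/- SD.

    A is bounded in (0, 1.05] (slightly above 1 to tolerate noise at
    saturation) and kobs in [0, inf).  Replicates that fail to converge,
    or whose signal never rises meaningfully above zero (kobs
    unidentifiable), are flagged and excluded from the mean.
    """
    t = tc.times_min
    if t.size < 3:
        raise ValueError("need at least 3 time points per replicate")
    n = tc.n_reps
    A = np.full(n, np.nan)
    k = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    flags: List[str] = []
    for r in range(n):
        y = tc.fraction[r]
        if y.max() < 0.02:
            flags.append(f"{tc.replicate_ids[r]}: signal ~0, kobs unidentifiable")
            k[r] = 0.0
            continue
        p0 = _initial_guess(t, y)
        try:
            popt, _ = curve_fit(_monoexp, t, y, p0=p0,
                                bounds=([1e-6, 0.0], [1.05, np.inf]),
                                maxfev=10000)
        except RuntimeError:
            flags.append(f"{tc.replicate_ids[r]}: fit did not converge")
            continue
        A[r], k[r] = popt
        ok[r] = True
    if flags:
        warnings.warn("; ".join(flags), stacklevel=2)
    if ok.any():
        a_mean = float(A[ok].mean())
        k_mean = float(k[ok].mean())
        a_sd = float(A[ok].std(ddof=1)) if ok.sum() >= 2 else None
        k_sd = float(k[ok].std(ddof=1)) if ok.sum() >= 2 else None
    else:
        a_mean = k_mean = float("nan")
        a_sd = k_sd = None
    return CleavageFit(A=A, kobs=k, converged=ok, A_mean=a_mean,
                       kobs_mean=k_mean, A_sd=a_sd, kobs_sd=k_sd, flags=flags)


def rate_fold_change(fit_a: CleavageFit, fit_b: CleavageFit) -> tuple:
    """kobs fold-change a/b with first-order propagated SD.

    The replicate SDs enter through the standard errors of the two mean
    rates: Var(f)/f^2 = (sd_a/k_a)^2/n_a + (sd_b/k_b)^2/n_b.  The SD is
    None when either fit lacks a replicate SD.
    """
    if not (fit_a.kobs_mean > 0 and fit_b.kobs_mean > 0):
        raise ValueError("fold change requires positive kobs in both fits")
    fold = fit_a.kobs_mean / fit_b.kobs_mean
    if fit_a.kobs_sd is None or fit_b.kobs_sd is None:
        return fold, None
    n_a, n_b = int(fit_a.converged.sum()), int(fit_b.converged.sum())
    rel = math.hypot(fit_a.kobs_sd / fit_a.kobs_mean / math.sqrt(n_a),
                     fit_b.kobs_sd / fit_b.kobs_mean / math.sqrt(n_b))
    return fold, fold * rel
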