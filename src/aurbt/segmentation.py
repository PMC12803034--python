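"""Change-point segmentation of rotor-angle series under an OU model.

The observed angle within a dwell is modeled as a stationary
Ornstein--Uhlenbeck process around a free segment mean; the global
noise parameters (tau_c, sigma) are fixed from a baseline portion of
the trace recorded before protein is introduced, so the only free
parameters are the per-segment mean and the change-point times.

The exact AR(1) discretization makes the likelihood a sum of
independent Gaussian innovation terms

    z_n = y_n - a y_{n-1} ~ N(mu (1 - a), sigma^2 (1 - a^2)),
    a = exp(-dt / tau_c),

so each segment's cost is an ordinary within-segment sum of squares of
innovations, evaluated in O(1) from cumulative sums.  The innovation
that straddles a change point is assigned to the later segment.
Search is by optimal partitioning with pruning (PELT); an exact dynamic
program over (position, number of changes) serves as an independent
oracle for small instances.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .core import Dwell, OUParams

DEFAULT_MIN_DWELL = 5


@dataclass
class Segmentation:
    """Result of a change-point search: dwells tiling the analyzed interval."""

    dwells: List[Dwell]
    ou: OUParams
    penalty: float
    log_likelihood: float
    dt: float = float("nan")

    @property
    def n_changes(self) -> int:
        return len(self.dwells) - 1

    @property
    def objective(self) -> float:
        """Penalized cost minimized by the search (lower is better)."""
        return -2.0 * self.log_likelihood + self.penalty * self.n_changes


def estimate_ou_params(baseline: np.ndarray, dt: float,
                       min_samples: int = 1000) -> OUParams:
    """Fit (tau_c, sigma) to a single-state baseline segment.

    Uses the stationary variance and the lag-1 autocorrelation, which
    for the exact discretization equal sigma^2 and exp(-dt/tau_c); this
    matches conditional maximum likelihood to O(1/n).  A non-positive
    lag-1 autocorrelation (white-noise degenerate limit) is flagged with
    a warning and tau_c is reported below dt.
    """
    y = np.asarray(baseline, dtype=float)
    if y.size < min_samples:
        raise ValueError(f"baseline needs >= {min_samples} samples, got {y.size}")
    if not dt > 0:
        raise ValueError("dt must be positive")
    d = y - y.mean()
    var = float(d @ d) / y.size
    if var <= 0:
        raise ValueError("baseline has non-positive variance")
    r1 = float(d[1:] @ d[:-1]) / (d @ d)
    if r1 <= 0:
        warnings.warn("lag-1 autocorrelation <= 0: noise indistinguishable from "
                      "white at this sampling; reporting tau_c < dt", stacklevel=2)
        return OUParams(tau_c=0.5 * dt, sigma=math.sqrt(var))
    return OUParams(tau_c=-dt / math.log(r1), sigma=math.sqrt(var))


# ---------------------------------------------------------------------------
# innovation transform and segment costs
# ---------------------------------------------------------------------------

def _whiten(y: np.ndarray, a: float) -> np.ndarray:
    """Innovations z[k] = y[k+1] - a y[k], k = 0..n-2."""
    return y[1:] - a * y[:-1]


def _cumsums(z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    cz = np.concatenate([[0.0], np.cumsum(z)])
    cz2 = np.concatenate([[0.0], np.cumsum(z * z)])
    return cz, cz2


def _block_cost(cz: np.ndarray, cz2: np.ndarray, i: int, j: int) -> float:
    """Within-block sum of squares of z[i:j] around its mean (unscaled)."""
    m = j - i
    s = cz[j] - cz[i]
    return (cz2[j] - cz2[i]) - s * s / m


@njit(cache=False)
def _pelt(cz, cz2, s2, penalty, minlen):  # pragma: no cover - numba kernel
    M = cz.shape[0] - 1
    F = np.full(M + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(M + 1, np.int64)
    cand = np.empty(M + 1, np.int64)
    cand[0] = 0
    ncand = 1
    for t in range(minlen, M + 1):
        # candidate s = t - minlen becomes usable once F[s] exists (s >= minlen)
        if t - minlen >= minlen:
            cand[ncand] = t - minlen
            ncand += 1
        best = np.inf
        arg = 0
        for ii in range(ncand):
            st = cand[ii]
            m = t - st
            if m < minlen:
                continue
            sz = cz[t] - cz[st]
            ss = (cz2[t] - cz2[st]) - sz * sz / m
            val = F[st] + ss / s2 + penalty
            if val < best:
                best = val
                arg = st
        F[t] = best
        last[t] = arg
        # conservative pruning (slack = penalty keeps optimality with minlen)
        keep = 0
        for ii in range(ncand):
            st = cand[ii]
            m = t - st
            if m >= minlen:
                sz = cz[t] - cz[st]
                ss = (cz2[t] - cz2[st]) - sz * sz / m
                if F[st] + ss / s2 > best + penalty:
                    continue
            cand[keep] = st
            keep += 1
        ncand = keep
    return F, last


def _backtrack(last: np.ndarray) -> List[int]:
    breaks: List[int] = []
    t = last.shape[0] - 1
    while t > 0:
        s = int(last[t])
        if s > 0:
            breaks.append(s)
        t = s
    return breaks[::-1]


def _dwells_from_breaks(y: np.ndarray, breaks: Sequence[int], a: float,
                        dt: float, t0: float = 0.0) -> List[Dwell]:
    """Build dwell list from innovation-space break indices.

    Break b (innovation index) puts the change between samples b and
    b+1, i.e. a new segment starting at sample b+1.  The reported mean
    is the conditional ML mean from the segment's interior innovations
    (the boundary-crossing innovation enters the cost of the later
    segment but not its mean, so a noiseless step yields exact means).
    """
    n = y.size
    edges = [0] + [b + 1 for b in breaks] + [n]
    dwells = []
    for i, j in zip(edges[:-1], edges[1:]):
        z_int = y[i + 1:j] - a * y[i:j - 1]  # interior innovations
        if z_int.size and a < 1.0:
            mean = float(z_int.mean()) / (1.0 - a)
        else:
            mean = float(y[i:j].mean())
        dwells.append(Dwell(t_start=t0 + i * dt, t_end=t0 + j * dt,
                            mean_level=mean, n_samples=j - i, units="turns"))
    return dwells


def _loglik(z: np.ndarray, breaks: Sequence[int], s2: float) -> float:
    """Gaussian log-likelihood of innovations given the fitted block means."""
    cz, cz2 = _cumsums(z)
    edges = [0] + list(breaks) + [z.size]
    ss = sum(_block_cost(cz, cz2, i, j) for i, j in zip(edges[:-1], edges[1:]))
    return -0.5 * ss / s2 - 0.5 * z.size * math.log(2.0 * math.pi * s2)


def _prepare(series: np.ndarray, ou: OUParams, dt: float,
             min_dwell_samples: int):
    y = np.ascontiguousarray(series, dtype=float)
    if y.size < 2 * min_dwell_samples:
        raise ValueError(
            f"series of {y.size} samples is shorter than 2 x min dwell "
            f"({min_dwell_samples})")
    a = ou.ar1_coeff(dt)
    s = ou.innovation_sd(dt)
    z = _whiten(y, a)
    if s > 0:
        s2 = s * s
    else:
        # noiseless limit: use the empirical innovation scale so the
        # penalty keeps its meaning; a constant series stays one dwell
        v = float(np.var(z))
        s2 = v if v > 0 else 1.0
    return y, a, z, s2


def segment_trace(series: np.ndarray, ou: OUParams, dt: float,
                  penalty: Optional[float] = None,
                  min_dwell_samples: int = DEFAULT_MIN_DWELL,
                  t0: float = 0.0) -> Segmentation:
    """Penalized OU change-point segmentation (optimal partitioning, PELT).

    Minimizes sum of per-segment innovation sums of squares (scaled by
    the innovation variance) plus ``penalty`` per change point.  The
    default penalty is BIC-style, 2 ln(n) per change point (one mean and
    one breakpoint per extra segment).  ``ou`` is fixed globally and
    never re-fit per segment.
    """
    y, a, z, s2 = _prepare(series, ou, dt, min_dwell_samples)
    M = z.size
    if penalty is None:
        penalty = 2.0 * math.log(M)
    cz, cz2 = _cumsums(z)
    _, last = _pelt(cz, cz2, s2, float(penalty), int(min_dwell_samples))
    breaks = _backtrack(last)
    dwells = _dwells_from_breaks(y, breaks, a, dt, t0)
    return Segmentation(dwells=dwells, ou=ou, penalty=float(penalty),
                        log_likelihood=_loglik(z, breaks, s2), dt=dt)


def oracle_segment(series: np.ndarray, ou: OUParams, dt: float,
                   max_changes: int = 3,
                   penalty: Optional[float] = None,
                   min_dwell_samples: int = DEFAULT_MIN_DWELL,
                   t0: float = 0.0) -> Segmentation:
    """Exact global optimum of the same penalized objective (small inputs).

    Dynamic program over (number of changes, position): guaranteed to
    reach the global optimum over all placements of up to
    ``max_changes`` change points, for series up to a few thousand
    samples.  Used as an independent oracle for ``segment_trace``.
    """
    y, a, z, s2 = _prepare(series, ou, dt, min_dwell_samples)
    M = z.size
    if M > 4000:
        raise ValueError("oracle_segment instance too large (> 4000 samples)")
    if max_changes > 3:
        raise ValueError("oracle_segment supports at most 3 change points")
    if penalty is None:
        penalty = 2.0 * math.log(M)
    cz, cz2 = _cumsums(z)
    minlen = int(min_dwell_samples)

    # cost[i, j) for all admissible blocks, vectorized per right edge
    idx = np.arange(M + 1)
    # D[k][t]: best cost of z[0:t] split into k+1 blocks; P[k][t]: argmin break
    K = int(max_changes)
    D = np.full((K + 1, M + 1), np.inf)
    P = np.zeros((K + 1, M + 1), dtype=int)
    m0 = idx
    with np.errstate(invalid="ignore", divide="ignore"):
        D[0] = np.where(m0 >= minlen,
                        cz2 - np.where(m0 > 0, cz * cz / np.maximum(m0, 1), 0.0),
                        np.inf)
    D[0, 0] = np.inf
    for k in range(1, K + 1):
        for t in range((k + 1) * minlen, M + 1):
            s_lo, s_hi = k * minlen, t - minlen + 1
            s = idx[s_lo:s_hi]
            m = t - s
            sz = cz[t] - cz[s]
            cost = (cz2[t] - cz2[s]) - sz * sz / m
            tot = D[k - 1, s_lo:s_hi] + cost
            j = int(np.argmin(tot))
            D[k, t] = tot[j]
            P[k, t] = s[j]

    totals = D[:, M] / s2 + penalty * np.arange(K + 1)
    k_best = int(np.nanargmin(totals))
    breaks: List[int] = []
    t = M
    for k in range(k_best, 0, -1):
        t = int(P[k, t])
        breaks.append(t)
    breaks = breaks[::-1]
    dwells = _dwells_from_breaks(y, breaks, a, dt, t0)
    return Segmentation(dwells=dwells, ou=ou, penalty=float(penalty),
                        log_likelihood=_loglik(z, breaks, s2), dt=dt)


def _enumerate_segment(series: np.ndarray, ou: OUParams, dt: float,
                       max_changes: int = 2,
                       penalty: Optional[float] = None,
                       min_dwell_samples: int = DEFAULT_MIN_DWELL) -> Segmentation:
    """Literal brute-force enumeration over all break placements (tiny inputs).

    Exists to validate the dynamic-programming oracle; combinatorial in
    ``max_changes``.
    """
    y, a, z, s2 = _prepare(series, ou, dt, min_dwell_samples)
    M = z.size
    if M > 600:
        raise ValueError("enumeration oracle limited to 600 samples")
    if penalty is None:
        penalty = 2.0 * math.log(M)
    cz, cz2 = _cumsums(z)
    minlen = int(min_dwell_samples)

    best = (math.inf, ())
    for k in range(max_changes + 1):
        for combo in itertools.combinations(range(minlen, M - minlen + 1), k):
            edges = (0,) + combo + (M,)
            if any(b - a_ < minlen for a_, b in zip(edges[:-1], edges[1:])):
                continue
            cost = sum(_block_cost(cz, cz2, i, j)
                       for i, j in zip(edges[:-1], edges[1:])) / s2
            obj = cost + penalty * k
            if obj < best[0] - 1e-12:
                best = (obj, combo)
    breaks = list(best[1])
    dwells = _dwells_from_breaks(y, breaks, a, dt)
    return Segmentation(dwells=dwells, ou=ou, penalty=float(penalty),
                        log_likelihood=_loglik(z, breaks, s2), dt=dt)


def decimate(series: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample.

    Because the OU parameters are expressed in seconds, the same
    (tau_c, sigma) remain exact at the decimated sampling interval
    factor * dt; only dt changes.
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    return np.asarray(series)[::factor]
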