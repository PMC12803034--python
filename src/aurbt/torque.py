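"""Torque-driven (twist-ramp) analysis.

Torque is read out from the angular deflection of the transducer
segment, tau = kappa_t (theta - psi), converted to base pairs unwound
via

    dtheta0(bp) = h (tau - tau_B) / (2 pi kappa_rad),   tau_B = kappa theta,

kinetics are binned by the instantaneous imposed twist (bins with fewer
than 3 sampled transitions for a pair are excluded), and the linear
twist-dependence models

    ln K_ij(theta)    = beta kappa dtheta_ij theta - beta dG_ij(0)
    ln k_ij(theta)    = beta kappa dtheta_dag_ij theta + ln k_ij(0)

are fit by weighted least squares, yielding the twist change dtheta_ij,
the zero-twist free energy dG_ij(0), and the fractional barrier
position dtheta_dag/dtheta used for landscape display.  Here beta kappa
is the tether's torsional energy stiffness per turn^2 divided by kBT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .core import Dwell
from .kinetics import Landscape, RateEstimate
from .states import StateModel
from .synth import TetherSpec, Trace, TWO_PI

MIN_TRANSITIONS_PER_BIN = 3


@dataclass
class TorqueSeries:
    """Torque, B-DNA reference torque, and unwinding derived from a ramp trace."""

    theta_turns: np.ndarray       # zero-referenced imposed twist
    torque_pNnm: np.ndarray       # tau from the transducer deflection
    torque_B_pNnm: Optional[np.ndarray] = None  # tau_B = kappa_turn * theta
    unwound_bp: Optional[np.ndarray] = None
    dt: float = float("nan")

    def __post_init__(self) -> None:
        for arr in (self.torque_B_pNnm, self.unwound_bp):
            if arr is not None and len(arr) != len(self.theta_turns):
                raise ValueError("series lengths must match")


@dataclass
class TwistBin:
    """Per-twist-bin transition counts, occupancy, and rates."""

    theta_center: float
    rates: List[RateEstimate]

    def rate_for(self, pair: Tuple[str, str]) -> Optional[RateEstimate]:
        for r in self.rates:
            if r.pair == pair:
                return r
        return None


@dataclass
class TwistFit:
    """Linear twist-dependence fit for one state pair."""

    pair: Tuple[str, str]
    slope_lnK: float              # per turn
    intercept_lnK: float
    se_slope_lnK: float
    se_intercept_lnK: float
    delta_theta_turns: float      # slope / (beta kappa)
    dG0_kBT: float                # -intercept
    slope_lnk_fwd: Optional[float] = None
    se_slope_lnk_fwd: Optional[float] = None
    lnk0_fwd: Optional[float] = None
    barrier_fraction: Optional[float] = None  # dtheta_dag / dtheta (display)
    theta_range_lnk: Optional[Tuple[float, float]] = None
    n_bins: int = 0

    @property
    def delta_theta_bp(self) -> float:
        """Twist change expressed in bp at 10.5 bp/turn (display aid)."""
        return -self.delta_theta_turns * 10.5


# ---------------------------------------------------------------------------
# torque computation and conversion
# ---------------------------------------------------------------------------

def compute_torque(trace: Trace, zero_offset_turns: float = 0.0) -> TorqueSeries:
    """Torque from the transducer deflection: tau = kappa_t (theta - psi).

    ``zero_offset_turns`` is the pre-calibrated zero-torque magnet
    position (found experimentally from maximum tether extension),
    subtracted from the magnet angle before anything else.
    """
    if trace.mode != "ramp" or trace.magnet_turns is None:
        raise ValueError("compute_torque requires a ramp-mode trace with magnet_turns")
    theta = trace.magnet_turns - zero_offset_turns
    tau = trace.tether.kappa_t_turn * (theta - trace.rotor_turns)
    return TorqueSeries(theta_turns=theta, torque_pNnm=tau, dt=trace.dt)


def fit_tether_stiffness(torque: np.ndarray, theta: np.ndarray,
                         mask: Optional[np.ndarray] = None) -> Tuple[float, float]:
    """Tether torsional stiffness from the slope of torque vs twist.

    Fit is restricted to closed-state spans (``mask``), where tau =
    kappa_turn * theta.  Returns (kappa_rad, intercept_pNnm); the
    intercept is retained as a residual zero check.
    """
    tau = np.asarray(torque, dtype=float)
    th = np.asarray(theta, dtype=float)
    if mask is not None:
        tau, th = tau[mask], th[mask]
    if tau.size < 10:
        raise ValueError("need >= 10 samples on closed-state spans")
    if np.ptp(th) == 0:
        raise ValueError("zero twist variance: stiffness not identifiable")
    slope, intercept = np.polyfit(th, tau, 1)  # pN nm per turn
    return float(slope) / TWO_PI, float(intercept)


def torque_to_unwinding(torque: TorqueSeries, kappa_rad: float,
                        helicity: float = 10.5) -> TorqueSeries:
    """Convert torque to base pairs unwound.

    dtheta0(bp) = h (tau - tau_B) / (2 pi kappa_rad), with tau_B =
    (2 pi kappa_rad) theta the expected torque of unperturbed B-DNA;
    positive values mean unwinding.  Returns a new TorqueSeries with
    ``torque_B_pNnm`` and ``unwound_bp`` filled in.
    """
    if not kappa_rad > 0:
        raise ValueError("kappa must be positive")
    tau_B = TWO_PI * kappa_rad * torque.theta_turns
    unwound = helicity * (torque.torque_pNnm - tau_B) / (TWO_PI * kappa_rad)
    return TorqueSeries(theta_turns=torque.theta_turns,
                        torque_pNnm=torque.torque_pNnm,
                        torque_B_pNnm=tau_B, unwound_bp=unwound, dt=torque.dt)


def twist_density(imposed_turns: float, tether: TetherSpec) -> float:
    """Supercoiling density in percent: 100 * turns / Lk0, signed."""
    return 100.0 * imposed_turns / tether.lk0


# ---------------------------------------------------------------------------
# twist-binned kinetics
# ---------------------------------------------------------------------------

def bin_kinetics_by_twist(dwells: Sequence[Dwell],
                          theta_of_t: Callable[[np.ndarray], np.ndarray],
                          bin_width_turns: float = 0.5,
                          theta_range: Optional[Tuple[float, float]] = None,
                          occupancy_dt: float = 0.01,
                          min_transitions: int = MIN_TRANSITIONS_PER_BIN
                          ) -> List[TwistBin]:
    """Bin transition counts and occupancy by the instantaneous imposed twist.

    Each dwell's lifetime is spread over the bins its theta(t) visits by
    midpoint sampling at resolution ``occupancy_dt`` (the dwell's total
    contribution equals its exact duration, so a single bin spanning
    all twist reduces exactly to the plain rate estimator); each
    transition is counted in the bin of theta at the transition time
    (the end of the departing dwell).  Pairs with fewer than
    ``min_transitions`` transitions in a bin are dropped from that bin.
    """
    seq = [d for d in dwells if d.state is not None]
    if len(seq) < 2:
        raise ValueError("need at least 2 labeled dwells")
    if not callable(theta_of_t):
        const = float(theta_of_t)
        theta_of_t = lambda t: np.full(np.shape(t), const)  # noqa: E731
    t0, t1 = seq[0].t_start, seq[-1].t_end
    probe = np.atleast_1d(np.asarray(theta_of_t(np.linspace(t0, t1, 2049)), dtype=float))
    if theta_range is None:
        lo = math.floor(probe.min() / bin_width_turns) * bin_width_turns
        hi = math.ceil(probe.max() / bin_width_turns) * bin_width_turns
        if hi <= lo:
            hi = lo + bin_width_turns
    else:
        lo, hi = theta_range
    edges = np.arange(lo, hi + 0.5 * bin_width_turns, bin_width_turns)
    nbins = edges.size - 1
    centers = 0.5 * (edges[:-1] + edges[1:])

    states = sorted({d.state for d in seq})
    smap = {s: i for i, s in enumerate(states)}
    occ = np.zeros((len(states), nbins))
    for d in seq:
        m = max(1, int(math.ceil(d.duration / occupancy_dt)))
        ts = d.t_start + (np.arange(m) + 0.5) * (d.duration / m)
        th = np.asarray(theta_of_t(ts), dtype=float)
        bi = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, nbins - 1)
        np.add.at(occ[smap[d.state]], bi, d.duration / m)

    # transitions: at the end of each dwell but the last
    counts: Dict[Tuple[int, Tuple[str, str]], int] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        th = float(np.asarray(theta_of_t(a.t_end)))
        k = int(np.clip(np.searchsorted(edges, th, side="right") - 1, 0, nbins - 1))
        pair = (a.state, b.state)
        counts[(k, pair)] = counts.get((k, pair), 0) + 1

    bins: List[TwistBin] = []
    for k in range(nbins):
        rates = []
        for (kk, pair), n in sorted(counts.items()):
            if kk != k or n < min_transitions:
                continue
            T_i = occ[smap[pair[0]], k]
            if T_i > 0:
                rates.append(RateEstimate.from_counts(pair, n, T_i))
        if rates:
            bins.append(TwistBin(theta_center=float(centers[k]), rates=rates))
    return bins


# ---------------------------------------------------------------------------
# linear twist-dependence fits
# ---------------------------------------------------------------------------

def _wls(x: np.ndarray, y: np.ndarray, se: np.ndarray):
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=1.0 / se ** 2).fit()
    return (float(res.params[1]), float(res.params[0]),
            float(res.bse[1]), float(res.bse[0]))


def _auto_linear_region(x: np.ndarray, y: np.ndarray, se: np.ndarray,
                        r2_threshold: float = 0.8,
                        min_bins: int = 3) -> np.ndarray:
    """Largest contiguous run of bins whose weighted fit has R^2 >= threshold.

    The generative law is exactly linear, so on synthetic data this
    typically returns the full range; on real data it trims curved ends
    of the ln k vs twist relation.
    """
    n = x.size
    best = None
    for i in range(n):
        for j in range(n, i + min_bins - 1, -1):
            if best is not None and (j - i) <= (best[1] - best[0]):
                break
            xi, yi, si = x[i:j], y[i:j], se[i:j]
            if np.ptp(xi) == 0:
                continue
            X = sm.add_constant(xi)
            res = sm.WLS(yi, X, weights=1.0 / si ** 2).fit()
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = res.rsquared if np.isfinite(res.rsquared) else 0.0
            if r2 >= r2_threshold:
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
                break
    if best is None:
        best = (0, n)
    mask = np.zeros(n, dtype=bool)
    mask[best[0]:best[1]] = True
    return mask


def fit_twist_dependence(bins: Sequence[TwistBin], tether: TetherSpec,
                         pairs: Optional[Sequence[Tuple[str, str]]] = None,
                         lnk_region: Optional[Tuple[float, float]] = None,
                         r2_threshold: float = 0.8) -> List[TwistFit]:
    """Weighted linear fits of ln K and ln k versus imposed twist.

    For each pair, ln K_ij = ln(k_ij/k_ji) is assembled from bins where
    both directions survive the 3-transition exclusion, weighted by the
    propagated SE sqrt(1/N_ij + 1/N_ji).  The forward ln k fit runs over
    ``lnk_region`` if given, otherwise over an automatically selected
    approximately linear contiguous run of bins.  The fractional barrier
    position is the slope ratio dtheta_dag/dtheta (stiffness cancels).
    """
    if pairs is None:
        seen = set()
        for b in bins:
            for r in b.rates:
                i, j = r.pair
                if (j, i) not in seen:
                    seen.add((i, j))
        pairs = sorted(p for p in seen
                       if any(b.rate_for((p[1], p[0])) for b in bins))
    bk = tether.beta_kappa
    fits = []
    for (i, j) in pairs:
        th, lnK, seK = [], [], []
        th_f, lnk, sek = [], [], []
        for b in bins:
            fwd, rev = b.rate_for((i, j)), b.rate_for((j, i))
            if fwd is not None:
                th_f.append(b.theta_center)
                lnk.append(math.log(fwd.rate))
                sek.append(1.0 / math.sqrt(fwd.n_transitions))
            if fwd is not None and rev is not None:
                th.append(b.theta_center)
                lnK.append(math.log(fwd.rate / rev.rate))
                seK.append(math.sqrt(1.0 / fwd.n_transitions + 1.0 / rev.n_transitions))
        th, lnK, seK = map(np.asarray, (th, lnK, seK))
        if th.size < 3:
            warnings.warn(f"pair {i}->{j}: fewer than 3 usable twist bins; skipped",
                          stacklevel=2)
            continue
        if np.ptp(th) == 0:
            raise ValueError(f"pair {i}->{j}: all bins at a single twist; no fit")
        slope, intercept, se_s, se_i = _wls(th, lnK, seK)
        fit = TwistFit(pair=(i, j), slope_lnK=slope, intercept_lnK=intercept,
                       se_slope_lnK=se_s, se_intercept_lnK=se_i,
                       delta_theta_turns=slope / bk, dG0_kBT=-intercept,
                       n_bins=int(th.size))
        th_f, lnk, sek = map(np.asarray, (th_f, lnk, sek))
        if th_f.size >= 3 and np.ptp(th_f) > 0:
            if lnk_region is not None:
                m = (th_f >= lnk_region[0]) & (th_f <= lnk_region[1])
            else:
                order = np.argsort(th_f)
                th_f, lnk, sek = th_f[order], lnk[order], sek[order]
                m = _auto_linear_region(th_f, lnk, sek, r2_threshold)
            if m.sum() >= 3 and np.ptp(th_f[m]) > 0:
                sl_f, ic_f, se_sf, _ = _wls(th_f[m], lnk[m], sek[m])
                fit.slope_lnk_fwd = sl_f
                fit.se_slope_lnk_fwd = se_sf
                fit.lnk0_fwd = ic_f
                fit.theta_range_lnk = (float(th_f[m].min()), float(th_f[m].max()))
                if fit.delta_theta_turns != 0:
                    fit.barrier_fraction = sl_f / slope
        fits.append(fit)
    return fits


def twist_landscape(fits: Sequence[TwistFit], model: StateModel,
                    theta: float = 0.0) -> Landscape:
    """Free-energy landscape at imposed twist theta from the linear fits.

    Well energies cumulate dG_ij(theta) = dG_ij(0) - slope_lnK * theta
    (kBT) along the state order; well x-positions are the
    lifetime-weighted state centers (the fitted dtheta values are not
    used for positions).  Barriers sit at fractional position
    dtheta_dag/dtheta between wells, at energy well_i - ln k_ij(theta).
    """
    lut = {f.pair: f for f in fits}
    labels = list(model.labels)
    energies = [0.0]
    bx, be = [], []
    truncated = None
    n_kept = 1
    for a, b, xa, xb in zip(labels[:-1], labels[1:],
                            model.centers_bp[:-1], model.centers_bp[1:]):
        f = lut.get((a, b))
        if f is None:
            truncated = a
            break
        dG_theta = f.dG0_kBT - f.slope_lnK * theta
        energies.append(energies[-1] + dG_theta)
        frac = f.barrier_fraction if f.barrier_fraction is not None else 0.5
        bx.append(xa + frac * (xb - xa))
        if f.slope_lnk_fwd is not None:
            lnk_theta = f.lnk0_fwd + f.slope_lnk_fwd * theta
            be.append(energies[-2] - lnk_theta)
        else:
            be.append(float("nan"))
        n_kept += 1
    return Landscape(
        well_labels=tuple(labels[:n_kept]),
        well_x_bp=np.asarray(model.centers_bp[:n_kept], dtype=float),
        well_energy_kBT=np.asarray(energies),
        barrier_x_bp=np.asarray(bx),
        barrier_energy_kBT=np.asarray(be),
        truncated_after=truncated,
        theta_turns=theta,
    )
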