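"""Synthetic rotor-bead trajectories and cleavage time courses.

Emulates the statistical structure of gold rotor-bead tracking (AuRBT)
data: hidden-state switching among discrete DNA-unwinding levels
(closed ~0 bp, intermediate ~7 bp, open ~14 bp), Ornstein--Uhlenbeck
angular noise of the rotor bead, 5 kHz sampling, triangular magnet-twist
ramps, torque read-out through a transducer segment, and twist-dependent
transition rates following an exponential (linear-in-log) model.  Every
trace carries its ground-truth state path so parameter-recovery tests
can compare estimates against the generating values.

Sign convention: positive unwinding x (bp) absorbs -x/h turns of helical
twist; the remaining duplex torque is tau = kappa_turn * (theta + x/h).
The equilibrium-twist change of an unwinding transition i->j is
dtheta_ij = -(x_j - x_i)/h turns (negative), so ln K increases as theta
becomes more negative (underwinding favours unwinding).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import lfilter

from .core import Dwell, OUParams
from .cleavage import CleavageTimecourse

TWO_PI = 2.0 * math.pi

#: default sampling interval, s (5 kHz acquisition)
DEFAULT_DT = 1.0 / 5000.0


@dataclass(frozen=True)
class TetherSpec:
    """Mechanical description of the DNA tether and torque transducer.

    Parameters
    ----------
    length_bp : int
        Tether length N in base pairs.
    helicity : float
        B-DNA helical repeat h, bp per turn (10.5 by convention).
    kappa_rad : float
        Torsional stiffness of the full tether, pN nm/rad (slope of the
        torque-twist curve).
    kappa_t_rad : float
        Torsional stiffness of the transducer segment, pN nm/rad.
    kBT : float
        Thermal energy, pN nm.
    tension_pN : float
        Applied tension (metadata only).
    """

    length_bp: int = 5000
    helicity: float = 10.5
    kappa_rad: float = 0.24
    kappa_t_rad: float = 0.26
    kBT: float = 4.114
    tension_pN: float = 5.0

    def __post_init__(self) -> None:
        for name in ("length_bp", "helicity", "kappa_rad", "kappa_t_rad", "kBT", "tension_pN"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TetherSpec.{name} must be strictly positive")
        if not (10.0 <= self.helicity <= 11.0):
            raise ValueError(f"helicity must lie in [10, 11] bp/turn, got {self.helicity}")

    @property
    def lk0(self) -> float:
        """Relaxed linking number Lk0 = N / h (turns)."""
        return self.length_bp / self.helicity

    @property
    def kappa_turn(self) -> float:
        """Tether torque per imposed turn, pN nm/turn (= 2 pi kappa_rad)."""
        return TWO_PI * self.kappa_rad

    @property
    def kappa_t_turn(self) -> float:
        """Transducer torque per turn of deflection, pN nm/turn."""
        return TWO_PI * self.kappa_t_rad

    @property
    def kappa_energy_turn(self) -> float:
        """Torsional energy stiffness per turn^2, pN nm (= 4 pi^2 kappa_rad).

        The elastic energy of the tether is (1/2) kappa_rad phi^2 with phi
        in radians, i.e. (1/2) (4 pi^2 kappa_rad) theta^2 with theta in
        turns; this is the stiffness entering the twist-dependence of
        free energies and rates.
        """
        return TWO_PI * TWO_PI * self.kappa_rad

    @property
    def beta_kappa(self) -> float:
        """beta * kappa in 1/turn^2: twist-energy slope scale of ln K."""
        return self.kappa_energy_turn / self.kBT


class TriangularRamp:
    """Triangular magnet-twist waveform between two bounds.

    The magnets rotate at a constant ``rate_rpm`` (turns/min), reversing
    at ``low_turns`` and ``high_turns``.  The wave starts at ``start``
    moving in ``direction`` (+1 toward high first).
    """

    def __init__(self, low_turns: float = -5.0, high_turns: float = 7.5,
                 rate_rpm: float = 3.0, start: Optional[float] = None,
                 direction: int = 1):
        if not low_turns < high_turns:
            raise ValueError("ramp bounds must satisfy low_turns < high_turns")
        if not rate_rpm > 0:
            raise ValueError("rate_rpm must be positive")
        self.low = float(low_turns)
        self.high = float(high_turns)
        self.rate_rpm = float(rate_rpm)
        self.rate = rate_rpm / 60.0  # turns/s
        self.start = float(start) if start is not None else 0.0
        if not (self.low <= self.start <= self.high):
            raise ValueError("start must lie within the ramp bounds")
        self.direction = 1 if direction >= 0 else -1
        self.span = self.high - self.low
        self.period = 2.0 * self.span / self.rate

    def __call__(self, t):
        """theta(t) in turns; accepts scalars or arrays."""
        t = np.asarray(t, dtype=float)
        # phase measured from the low vertex of the triangular wave
        if self.direction > 0:
            phase0 = self.start - self.low
        else:
            phase0 = 2.0 * self.span - (self.start - self.low)
        u = np.mod(phase0 + self.rate * t, 2.0 * self.span)
        theta = self.low + np.where(u <= self.span, u, 2.0 * self.span - u)
        return theta if theta.ndim else float(theta)

    def vertex_times(self, t0: float, t1: float) -> np.ndarray:
        """Times of ramp reversals inside [t0, t1]."""
        if self.direction > 0:
            phase0 = self.start - self.low
        else:
            phase0 = 2.0 * self.span - (self.start - self.low)
        # vertices occur when phase = k * span
        k0 = math.ceil((phase0 + self.rate * t0) / self.span)
        k1 = math.floor((phase0 + self.rate * t1) / self.span)
        ks = np.arange(k0, k1 + 1, dtype=float)
        return (ks * self.span - phase0) / self.rate

    def range_in(self, t0: float, t1: float) -> Tuple[float, float]:
        """Exact min/max of theta over [t0, t1]."""
        pts = [self(t0), self(t1)]
        pts.extend(self(tv) for tv in self.vertex_times(t0, t1))
        return float(min(pts)), float(max(pts))


ThetaLike = Union[float, TriangularRamp, Callable[[float], float]]


@dataclass(frozen=True)
class StateSpec:
    """Discrete R-loop states and their twist-dependent transition rates.

    Each state s has an unwinding level x_s (bp).  Directed transitions
    (i, j) carry a zero-twist rate k_ij(0) (1/s), an equilibrium-twist
    change dtheta_ij = -(x_j - x_i)/h (turns) and a transition-state
    twist change dtheta_dag_ij (turns) lying between 0 and dtheta_ij.
    Rates follow

        ln k_ij(theta) = beta kappa dtheta_dag_ij theta + ln k_ij(0)

    with beta kappa in 1/turn^2 taken from the tether, so that

        ln K_ij(theta) = beta kappa dtheta_ij theta + ln K_ij(0)

    is linear in the imposed twist theta (detailed-balance consistency:
    dtheta_dag_ji = dtheta_dag_ij - dtheta_ij).
    """

    labels: Tuple[str, ...]
    unwinding_bp: Tuple[float, ...]
    base_rates: Dict[Tuple[str, str], float]
    helicity: float = 10.5
    barrier_fraction: float = 0.4
    delta_theta: Dict[Tuple[str, str], float] = field(default_factory=dict)
    barrier_twist: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        x = tuple(float(v) for v in self.unwinding_bp)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "unwinding_bp", x)
        if len(labels) != len(x):
            raise ValueError("labels and unwinding_bp must have equal length")
        if any(v < 0 for v in x):
            raise ValueError("unwinding levels must be non-negative")
        if any(b <= a for a, b in zip(x, x[1:])):
            raise ValueError("unwinding levels must be strictly increasing")
        if any(k < 0 for k in self.base_rates.values()):
            raise ValueError("base rates must be non-negative")
        xmap = dict(zip(labels, x))
        dtheta = dict(self.delta_theta)
        for (i, j) in self.base_rates:
            if i not in xmap or j not in xmap:
                raise ValueError(f"unknown state in rate pair ({i}, {j})")
            dtheta.setdefault((i, j), -(xmap[j] - xmap[i]) / self.helicity)
        barrier = dict(self.barrier_twist)
        for (i, j) in self.base_rates:
            if (i, j) in barrier:
                continue
            if (j, i) in barrier:
                # detailed-balance-consistent reverse barrier
                barrier[(i, j)] = barrier[(j, i)] + dtheta[(i, j)]
            else:
                barrier[(i, j)] = self.barrier_fraction * dtheta[(i, j)]
        for (i, j), bt in barrier.items():
            dt_ij = dtheta.get((i, j))
            if dt_ij is None:
                continue
            lo, hi = sorted((0.0, dt_ij))
            if not (lo - 1e-12 <= bt <= hi + 1e-12):
                raise ValueError(
                    f"barrier twist for ({i}->{j}) must lie between 0 and "
                    f"dtheta={dt_ij:.4f}, got {bt:.4f}"
                )
        object.__setattr__(self, "delta_theta", dtheta)
        object.__setattr__(self, "barrier_twist", barrier)

    # -- rate law -----------------------------------------------------

    def unwinding_of(self, label: str) -> float:
        return self.unwinding_bp[self.labels.index(label)]

    def rate(self, i: str, j: str, theta: float, beta_kappa: float) -> float:
        """k_ij(theta) = k_ij(0) exp(beta kappa dtheta_dag_ij theta)."""
        k0 = self.base_rates.get((i, j), 0.0)
        if k0 == 0.0:
            return 0.0
        return k0 * math.exp(beta_kappa * self.barrier_twist[(i, j)] * theta)

    def ln_K(self, i: str, j: str, theta: float, beta_kappa: float) -> float:
        """ln K_ij(theta), from the generating rate law (analytic)."""
        kf = self.base_rates.get((i, j), 0.0)
        kr = self.base_rates.get((j, i), 0.0)
        if kf <= 0 or kr <= 0:
            raise ValueError(f"both directions of ({i}, {j}) need positive base rates")
        return math.log(kf / kr) + beta_kappa * self.delta_theta[(i, j)] * theta

    def exits(self, i: str) -> List[str]:
        return [j for (a, j) in self.base_rates if a == i and self.base_rates[(a, j)] > 0]

    @classmethod
    def default_cio(cls, k_ci: float = 0.2, k_ic: float = 0.5,
                    k_io: float = 0.1, k_oi: float = 0.3,
                    levels_bp: Sequence[float] = (0.0, 7.0, 14.0),
                    helicity: float = 10.5,
                    barrier_fraction: float = 0.4) -> "StateSpec":
        """Three-state closed/intermediate/open model with sequential kinetics."""
        return cls(
            labels=("C", "I", "O"),
            unwinding_bp=tuple(levels_bp),
            base_rates={("C", "I"): k_ci, ("I", "C"): k_ic,
                        ("I", "O"): k_io, ("O", "I"): k_oi},
            helicity=helicity,
            barrier_fraction=barrier_fraction,
        )


@dataclass
class Trace:
    """Uniformly sampled rotor-bead angle series with tether metadata."""

    dt: float
    rotor_turns: np.ndarray
    mode: str  # "relaxed" | "ramp"
    tether: TetherSpec
    seed: Optional[int] = None
    magnet_turns: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.mode not in ("relaxed", "ramp"):
            raise ValueError(f"unknown trace mode {self.mode!r}")
        if (self.magnet_turns is not None) != (self.mode == "ramp"):
            raise ValueError("magnet_turns must be present iff mode == 'ramp'")
        if self.magnet_turns is not None and len(self.magnet_turns) != len(self.rotor_turns):
            raise ValueError("rotor and magnet series must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.rotor_turns)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class GroundTruth:
    """True hidden-state path behind a synthetic trace."""

    switch_times: np.ndarray
    state_labels: List[str]  # one per inter-switch interval (len = switches + 1)
    duration: float
    spec: StateSpec
    ou: Optional[OUParams] = None

    def __post_init__(self) -> None:
        st = np.asarray(self.switch_times, dtype=float)
        if len(self.state_labels) != len(st) + 1:
            raise ValueError("need one state label per inter-switch interval")
        if len(st) and (np.any(np.diff(st) <= 0) or st[0] <= 0 or st[-1] >= self.duration):
            raise ValueError("switch times must be strictly increasing within the trace")
        unknown = set(self.state_labels) - set(self.spec.labels)
        if unknown:
            raise ValueError(f"labels not in spec: {sorted(unknown)}")
        object.__setattr__(self, "switch_times", st)

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Index into spec.labels of the occupied state at each time."""
        interval = np.searchsorted(self.switch_times, np.asarray(t, dtype=float), side="right")
        lab_idx = np.array([self.spec.labels.index(s) for s in self.state_labels])
        return lab_idx[interval]

    def unwinding_at(self, t: np.ndarray) -> np.ndarray:
        """True unwinding x(t) in bp."""
        x = np.asarray(self.spec.unwinding_bp)
        return x[self.state_at(t)]

    def to_dwells(self, units: str = "bp") -> List[Dwell]:
        """Ground-truth dwell list (state labels attached)."""
        edges = np.concatenate([[0.0], self.switch_times, [self.duration]])
        out = []
        for k, lab in enumerate(self.state_labels):
            x = self.spec.unwinding_of(lab)
            level = x if units == "bp" else x / self.spec.helicity
            out.append(Dwell(t_start=edges[k], t_end=edges[k + 1], mean_level=level,
                             n_samples=0, units=units, state=lab))
        return out


# ---------------------------------------------------------------------------
# hidden-state path simulation
# ---------------------------------------------------------------------------

def _theta_range(theta_of_t: ThetaLike, t0: float, t1: float,
                 pad: bool) -> Tuple[float, float, float]:
    """(theta_min, theta_max, bound_safety) over [t0, t1]."""
    if isinstance(theta_of_t, TriangularRamp):
        lo, hi = theta_of_t.range_in(t0, t1)
        return lo, hi, 1.0
    if callable(theta_of_t):
        ts = np.linspace(t0, t1, 33)
        th = np.array([float(theta_of_t(t)) for t in ts])
        # sampled extrema: pad the thinning bound for safety
        return float(th.min()), float(th.max()), 1.05 if pad else 1.0
    v = float(theta_of_t)
    return v, v, 1.0


def simulate_state_path(spec: StateSpec, duration: float,
                        theta_of_t: ThetaLike = 0.0,
                        tether: Optional[TetherSpec] = None,
                        seed: Optional[int] = None,
                        initial_state: Optional[str] = None,
                        rng: Optional[np.random.Generator] = None,
                        window_s: Optional[float] = None) -> GroundTruth:
    """Simulate the hidden-state continuous-time Markov path.

    At constant twist this is an exact Gillespie simulation.  Under a
    twist ramp, rates are time-dependent and switching is simulated
    exactly by thinning: within short windows (over which theta varies
    little) proposals are drawn at an upper bound of the total exit rate
    of the current state and accepted with probability (true rate)/
    (bound).  Because rates are monotone-exponential in theta, the bound
    is evaluated at the window's twist extremes.

    Raises ``ValueError`` if any rate is non-finite over the visited
    twist range, naming the offending pair.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    tether = tether or TetherSpec()
    bk = tether.beta_kappa
    rng = rng if rng is not None else np.random.default_rng(seed)

    glo, ghi, _ = _theta_range(theta_of_t, 0.0, duration, pad=False)
    for (i, j) in spec.base_rates:
        for th in (glo, ghi):
            k = spec.rate(i, j, th, bk)
            if not math.isfinite(k):
                raise ValueError(
                    f"rate for transition {i}->{j} is non-finite at theta={th:.3g}"
                )

    if window_s is None:
        if isinstance(theta_of_t, TriangularRamp):
            window_s = 0.25 / theta_of_t.rate  # theta varies by <= 0.25 turn
        elif callable(theta_of_t):
            window_s = duration / 200.0
        else:
            window_s = duration  # constant twist: one window = exact Gillespie

    state = initial_state or spec.labels[0]
    t = 0.0
    switch_times: List[float] = []
    labels: List[str] = [state]

    while t < duration:
        t_w = min(duration, t + window_s)
        lo, hi, safety = _theta_range(theta_of_t, t, t_w, pad=True)
        exits = spec.exits(state)
        if not exits:
            break
        bound = safety * sum(max(spec.rate(state, j, lo, bk), spec.rate(state, j, hi, bk))
                             for j in exits)
        if bound <= 0:
            t = t_w
            continue
        while t < t_w:
            t_prop = t + rng.exponential(1.0 / bound)
            if t_prop >= t_w:
                t = t_w
                break
            t = t_prop
            th = float(theta_of_t(t)) if callable(theta_of_t) else float(theta_of_t)
            rates = np.array([spec.rate(state, j, th, bk) for j in exits])
            total = rates.sum()
            if rng.uniform() < total / bound:
                j = exits[rng.choice(len(exits), p=rates / total)]
                switch_times.append(t)
                labels.append(j)
                state = j
                break  # re-derive the bound for the new state

    return GroundTruth(switch_times=np.array(switch_times), state_labels=labels,
                       duration=duration, spec=spec, ou=None)


# ---------------------------------------------------------------------------
# observable traces
# ---------------------------------------------------------------------------

def _ou_series(mu: np.ndarray, ou: OUParams, dt: float,
               rng: np.random.Generator) -> np.ndarray:
    """OU observation mean-reverting toward a (possibly moving) mean series.

    Exact discretization y_n = mu_n + (y_{n-1} - mu_n) a + s xi_n with
    a = exp(-dt/tau_c), s = sigma sqrt(1 - a^2): the bead relaxes
    through tau_c after each state switch rather than jumping, which is
    both the physical behaviour and the generative counterpart of the
    segmentation likelihood.  Starts stationary around mu_0.
    """
    mu = np.asarray(mu, dtype=float)
    if ou.sigma == 0.0:
        return mu.copy()
    a = ou.ar1_coeff(dt)
    s = ou.innovation_sd(dt)
    # deviation from the current mean: d_n = a d_{n-1} + a (mu_{n-1} - mu_n) + s xi_n
    u = s * rng.standard_normal(mu.size)
    u[1:] += a * (mu[:-1] - mu[1:])
    u[0] = ou.sigma * rng.standard_normal()  # stationary start
    d = lfilter([1.0], [1.0, -a], u)
    return mu + d


def simulate_relaxed_trace(spec: StateSpec, ou: OUParams,
                           tether: Optional[TetherSpec] = None,
                           duration: float = 100.0, dt: float = DEFAULT_DT,
                           seed: Optional[int] = None) -> Tuple[Trace, GroundTruth]:
    """Torsionally relaxed assay: rotor angle reports unwinding directly.

    The rotor mean in turns is x_state / h; the observed angle
    mean-reverts toward it with the exact AR(1) discretization
    psi_n = mu_n + (psi_{n-1} - mu_n) a + sigma sqrt(1-a^2) xi_n,
    a = exp(-dt/tau_c), so the bead relaxes through tau_c after each
    state switch.
    """
    if not duration > 0 or not dt > 0:
        raise ValueError("duration and dt must be positive")
    if dt >= ou.tau_c and ou.sigma > 0:
        warnings.warn("dt >= tau_c: OU noise is nearly white at this sampling",
                      stacklevel=2)
    tether = tether or TetherSpec()
    ss = np.random.SeedSequence(seed)
    rng_path, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    path = simulate_state_path(spec, duration, 0.0, tether, rng=rng_path)
    path.ou = ou
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    mu = path.unwinding_at(t) / tether.helicity
    rotor = _ou_series(mu, ou, dt, rng_noise)
    trace = Trace(dt=dt, rotor_turns=rotor, mode="relaxed", tether=tether, seed=seed)
    return trace, path


def simulate_ramp_trace(spec: StateSpec, ou: OUParams,
                        tether: Optional[TetherSpec] = None,
                        ramp: Union[TriangularRamp, dict, None] = None,
                        duration: float = 500.0, dt: float = DEFAULT_DT,
                        seed: Optional[int] = None) -> Tuple[Trace, GroundTruth]:
    """Torque-driven assay: triangular magnet ramp, torque through the transducer.

    The instantaneous tether torque is tau(t) = kappa_turn (theta(t) +
    x(t)/h); the rotor-bead mean angle follows from the transducer
    deflection, psi_mean(t) = theta(t) - tau(t)/kappa_t_turn, and OU
    noise is added on top.  The hidden-state path is generated with
    theta(t)-dependent rates.
    """
    if not duration > 0 or not dt > 0:
        raise ValueError("duration and dt must be positive")
    tether = tether or TetherSpec()
    if ramp is None:
        ramp = TriangularRamp()
    elif isinstance(ramp, dict):
        ramp = TriangularRamp(low_turns=ramp.get("low_turns", -5.0),
                              high_turns=ramp.get("high_turns", 7.5),
                              rate_rpm=ramp.get("rate_rpm", 3.0),
                              start=ramp.get("start"),
                              direction=ramp.get("direction", 1))
    ss = np.random.SeedSequence(seed)
    rng_path, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    path = simulate_state_path(spec, duration, ramp, tether, rng=rng_path)
    path.ou = ou
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    theta = np.asarray(ramp(t), dtype=float)
    x = path.unwinding_at(t)
    tau = tether.kappa_turn * (theta + x / tether.helicity)
    psi_mean = theta - tau / tether.kappa_t_turn
    rotor = _ou_series(psi_mean, ou, dt, rng_noise)
    trace = Trace(dt=dt, rotor_turns=rotor, mode="ramp", tether=tether,
                  seed=seed, magnet_turns=theta)
    return trace, path


DEFAULT_CLEAVAGE_TIMES_MIN = (0.5, 1.0, 5.0, 10.0, 30.0, 60.0, 120.0)


def simulate_cleavage_timecourse(A: float, kobs_per_min: float,
                                 times_min: Sequence[float] = DEFAULT_CLEAVAGE_TIMES_MIN,
                                 noise_sd: float = 0.02, n_reps: int = 3,
                                 seed: Optional[int] = None) -> CleavageTimecourse:
    """Mono-exponential cleavage time course Y = A (1 - exp(-kobs t)) + noise.

    Per-replicate Gaussian noise is clipped to [0, 1] (gel band
    fractions are bounded).
    """
    times = np.asarray(times_min, dtype=float)
    if times.size == 0:
        raise ValueError("times_min must be non-empty")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if not (0 < A <= 1):
        raise ValueError("amplitude A must lie in (0, 1]")
    if kobs_per_min < 0:
        raise ValueError("kobs must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    clean = A * (1.0 - np.exp(-kobs_per_min * times))
    fracs = clean[None, :] + noise_sd * rng.standard_normal((n_reps, times.size))
    fracs = np.clip(fracs, 0.0, 1.0)
    return CleavageTimecourse(times_min=times, fraction=fracs,
                              replicate_ids=[f"rep{i + 1}" for i in range(n_reps)],
                              seed=seed)
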