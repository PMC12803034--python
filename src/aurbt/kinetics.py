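"""Equilibrium (fixed-twist) transition kinetics and free energies.

Rates are counted from labeled, merged dwell sequences: k_ij is the
number of i -> j transitions divided by the total time spent in state
i, with Poisson standard errors sqrt(N_ij)/T_i.  Counting starts after
the first transition event (the initial dwell, recorded before the
first R-loop event, is excluded from both counts and occupancy); the
final, right-censored dwell contributes occupancy but no exit.

Equilibrium constants, free-energy differences, and barrier heights
follow

    K_ij = k_ij / k_ji,   dG_ij = -ln K_ij (kBT),
    dG_dag_ij = -ln k_ij (kBT, rates in 1/s against an implicit unit
    attempt frequency; a display-level convention, not an absolute
    activation energy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Dwell
from .states import StateModel


@dataclass
class RateEstimate:
    """Transition rate k_ij = N_ij / T_i with Poisson error sqrt(N_ij)/T_i."""

    pair: Tuple[str, str]
    n_transitions: int
    occupancy_s: float
    rate: float
    se: float

    @classmethod
    def from_counts(cls, pair: Tuple[str, str], n: int, occupancy_s: float
                    ) -> "RateEstimate":
        if occupancy_s <= 0:
            raise ValueError(f"occupancy for {pair} must be positive")
        return cls(pair=pair, n_transitions=int(n), occupancy_s=float(occupancy_s),
                   rate=n / occupancy_s, se=math.sqrt(n) / occupancy_s)


@dataclass
class ThermoResult:
    """Equilibrium constant, free energy (kBT), and barrier heights for a pair."""

    pair: Tuple[str, str]
    K: float
    dG_kBT: float
    se_lnK: float
    barrier_kBT: Dict[str, float]  # {"fwd": -ln k_ij, "rev": -ln k_ji}


@dataclass
class Landscape:
    """Well and barrier positions/energies of the sequential landscape."""

    well_labels: Tuple[str, ...]
    well_x_bp: np.ndarray
    well_energy_kBT: np.ndarray
    barrier_x_bp: np.ndarray
    barrier_energy_kBT: np.ndarray
    truncated_after: Optional[str] = None
    theta_turns: float = 0.0


def transition_rates(dwells: Sequence[Dwell],
                     count_from_first_transition: bool = True,
                     include_final_occupancy: bool = True
                     ) -> List[RateEstimate]:
    """Count transitions and occupancy from a labeled dwell sequence.

    Pairs with zero occupancy are omitted.  Returns an empty list (with
    a warning) when no transitions remain after excluding the first.
    """
    seq = [d for d in dwells if d.state is not None]
    if len(seq) < 2:
        raise ValueError("need at least 2 labeled dwells after merging")
    start = 1 if count_from_first_transition else 0
    counts: Dict[Tuple[str, str], int] = {}
    occupancy: Dict[str, float] = {}
    for k in range(start, len(seq)):
        d = seq[k]
        is_final = k == len(seq) - 1
        if not is_final or include_final_occupancy:
            occupancy[d.state] = occupancy.get(d.state, 0.0) + d.duration
        if not is_final:
            pair = (d.state, seq[k + 1].state)
            counts[pair] = counts.get(pair, 0) + 1
    if not counts:
        warnings.warn("no transitions after the first event; no rates to report",
                      stacklevel=2)
        return []
    out = []
    for (i, j), n in sorted(counts.items()):
        if occupancy.get(i, 0.0) > 0:
            out.append(RateEstimate.from_counts((i, j), n, occupancy[i]))
    # observed states with occupancy but no exits toward some partner are
    # simply absent; rates are only reported for observed pairs
    return out


def derive_thermodynamics(rates: Sequence[RateEstimate]) -> List[ThermoResult]:
    """K, dG and barrier heights for every pair observed in both directions.

    The standard error of ln K is sqrt(1/N_ij + 1/N_ji) (Poisson
    propagation).  One-directional pairs are reported as missing, not
    infinite.
    """
    by_pair = {r.pair: r for r in rates}
    seen = set()
    out = []
    for (i, j), fwd in by_pair.items():
        if (i, j) in seen or (j, i) in seen:
            continue
        rev = by_pair.get((j, i))
        if rev is None or fwd.rate <= 0 or rev.rate <= 0:
            continue
        seen.add((i, j))
        K = fwd.rate / rev.rate
        out.append(ThermoResult(
            pair=(i, j),
            K=K,
            dG_kBT=-math.log(K),
            se_lnK=math.sqrt(1.0 / fwd.n_transitions + 1.0 / rev.n_transitions),
            barrier_kBT={"fwd": -math.log(fwd.rate), "rev": -math.log(rev.rate)},
        ))
    return out


def equilibrium_landscape(thermo: Sequence[ThermoResult], model: StateModel
                          ) -> Landscape:
    """Sequential free-energy landscape from adjacent-pair thermodynamics.

    Well x-positions are the lifetime-weighted state centers; well
    energies are cumulative sums of dG along the state order with the
    first (closed) state at 0.  Barriers sit midway between wells at
    this equilibrium stage (the torque-driven analysis refines their
    fractional positions) at energy well_i + dG_dag(i->j).  A missing
    adjacent pair truncates the landscape at the gap, flagged via
    ``truncated_after``.
    """
    lut = {}
    for t in thermo:
        lut[t.pair] = t
        lut[(t.pair[1], t.pair[0])] = ThermoResult(
            pair=(t.pair[1], t.pair[0]), K=1.0 / t.K, dG_kBT=-t.dG_kBT,
            se_lnK=t.se_lnK,
            barrier_kBT={"fwd": t.barrier_kBT["rev"], "rev": t.barrier_kBT["fwd"]})
    labels = list(model.labels)
    energies = [0.0]
    bx, be = [], []
    truncated = None
    n_kept = 1
    for a, b, xa, xb in zip(labels[:-1], labels[1:],
                            model.centers_bp[:-1], model.centers_bp[1:]):
        t = lut.get((a, b))
        if t is None:
            truncated = a
            break
        energies.append(energies[-1] + t.dG_kBT)
        bx.append(0.5 * (xa + xb))
        be.append(energies[-2] + t.barrier_kBT["fwd"])
        n_kept += 1
    return Landscape(
        well_labels=tuple(labels[:n_kept]),
        well_x_bp=np.asarray(model.centers_bp[:n_kept], dtype=float),
        well_energy_kBT=np.asarray(energies),
        barrier_x_bp=np.asarray(bx),
        barrier_energy_kBT=np.asarray(be),
        truncated_after=truncated,
    )
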