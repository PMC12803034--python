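"""Discrete R-loop state assignment from segmented dwells.

Dwell mean levels (in bp unwound) are clustered into the known states
(closed / intermediate / open, optionally the short-lived extended-open
O' excursions), adjacent same-state dwells are merged, and traces are
zeroed so the predominant closed state sits at 0 bp.  State centers are
lifetime-weighted mean unwinding values; boundaries between adjacent
states are the arithmetic means of adjacent centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import Dwell

DEFAULT_LABELS = ("C", "I", "O")


@dataclass
class StateModel:
    """Ordered state centers (lifetime-weighted, bp) and their boundaries."""

    labels: Tuple[str, ...]
    centers_bp: np.ndarray
    boundaries_bp: np.ndarray = field(default=None)
    oprime_label: Optional[str] = None  # dwells above the top boundary

    def __post_init__(self) -> None:
        self.centers_bp = np.asarray(self.centers_bp, dtype=float)
        if self.boundaries_bp is None:
            self.boundaries_bp = 0.5 * (self.centers_bp[:-1] + self.centers_bp[1:])
        self.boundaries_bp = np.asarray(self.boundaries_bp, dtype=float)
        if len(self.labels) != self.centers_bp.size:
            raise ValueError("one label per center required")
        if np.any(np.diff(self.centers_bp) <= 0):
            raise ValueError("state centers must be strictly increasing")
        if self.boundaries_bp.size != self.centers_bp.size - 1:
            raise ValueError("need n_states - 1 boundaries")
        for b, lo, hi in zip(self.boundaries_bp, self.centers_bp[:-1], self.centers_bp[1:]):
            if not (lo < b < hi):
                raise ValueError("each boundary must lie strictly between adjacent centers")

    def assign(self, level_bp: float) -> str:
        """State label for a dwell mean; ties on a boundary go to the lower state."""
        k = int(np.searchsorted(self.boundaries_bp, level_bp, side="left"))
        if self.oprime_label is not None and k == len(self.labels) - 1:
            # levels above the top center's upper reach are O' excursions:
            # anything beyond center_top + (center_top - boundary_top)
            top = self.centers_bp[-1] + (self.centers_bp[-1] - self.boundaries_bp[-1])
            if level_bp > top:
                return self.oprime_label
        return self.labels[k]


def dwell_levels_bp(dwells: Sequence[Dwell], helicity: float = 10.5) -> np.ndarray:
    """Dwell mean levels in bp (converting turns via the helical repeat)."""
    out = np.empty(len(dwells))
    for i, d in enumerate(dwells):
        out[i] = d.mean_level * helicity if d.units == "turns" else d.mean_level
    return out


def _weighted_centers(levels: np.ndarray, lifetimes: np.ndarray,
                      assign: np.ndarray, n_states: int) -> np.ndarray:
    centers = np.empty(n_states)
    for s in range(n_states):
        m = assign == s
        if not m.any():
            centers[s] = np.nan
        else:
            centers[s] = np.average(levels[m], weights=lifetimes[m])
    return centers


def cluster_states(dwells: Sequence[Dwell],
                   initial_centers: Optional[Sequence[float]] = None,
                   n_states: Optional[int] = None,
                   labels: Optional[Sequence[str]] = None,
                   helicity: float = 10.5,
                   max_iter: int = 100) -> StateModel:
    """1-D clustering of dwell means into discrete unwinding states.

    Assignment to the nearest center and lifetime-weighted center
    updates are iterated to a fixed point (a lifetime-weighted Lloyd
    iteration).  When the states are known a priori, pass
    ``initial_centers``; otherwise centers start at evenly spaced
    quantiles of the dwell-mean range.
    """
    if initial_centers is None and n_states is None:
        raise ValueError("give either initial_centers or n_states")
    levels = dwell_levels_bp(dwells, helicity)
    lifetimes = np.array([d.duration for d in dwells])
    if initial_centers is not None:
        centers = np.sort(np.asarray(initial_centers, dtype=float))
    else:
        qs = np.linspace(0, 1, int(n_states) + 2)[1:-1]
        centers = np.quantile(levels, qs)
        if np.unique(centers).size < n_states:
            raise ValueError("fewer distinct dwell levels than requested states")
    k = centers.size
    if np.unique(levels).size < k:
        raise ValueError("fewer distinct dwell levels than requested states")

    assign = np.argmin(np.abs(levels[:, None] - centers[None, :]), axis=1)
    for _ in range(max_iter):
        new_centers = _weighted_centers(levels, lifetimes, assign, k)
        # empty clusters keep their previous center
        new_centers = np.where(np.isnan(new_centers), centers, new_centers)
        new_assign = np.argmin(np.abs(levels[:, None] - new_centers[None, :]), axis=1)
        converged = np.array_equal(new_assign, assign) and np.allclose(new_centers, centers)
        centers, assign = new_centers, new_assign
        if converged:
            break

    if labels is None:
        labels = DEFAULT_LABELS[:k] if k <= len(DEFAULT_LABELS) else tuple(
            f"S{i}" for i in range(k))
    return StateModel(labels=tuple(labels), centers_bp=centers)


def assign_merge_zero(dwells: Sequence[Dwell], model: StateModel,
                      helicity: float = 10.5,
                      zero: bool = True) -> Tuple[List[Dwell], float, StateModel]:
    """Label dwells by state, merge same-state neighbours, zero the closed state.

    Consecutive dwells assigned to the same state are merged into one
    dwell whose mean is the lifetime-weighted mean of its parts.  All
    levels are then shifted so the lifetime-weighted mean of the
    predominant (most-occupied) lowest state is 0 bp; the applied offset
    and the re-centered state model are returned alongside the merged
    dwell list (levels in bp).
    """
    levels = dwell_levels_bp(dwells, helicity)
    labeled = [d.with_(mean_level=lv, units="bp", state=model.assign(lv))
               for d, lv in zip(dwells, levels)]

    merged: List[Dwell] = []
    for d in labeled:
        if merged and merged[-1].state == d.state and np.isclose(merged[-1].t_end, d.t_start):
            prev = merged[-1]
            w1, w2 = prev.duration, d.duration
            merged[-1] = prev.with_(
                t_end=d.t_end,
                mean_level=(prev.mean_level * w1 + d.mean_level * w2) / (w1 + w2),
                n_samples=prev.n_samples + d.n_samples,
            )
        else:
            merged.append(d)

    offset = 0.0
    if zero:
        occ = {}
        for d in merged:
            occ[d.state] = occ.get(d.state, 0.0) + d.duration
        lowest = model.labels[0]
        predominant = max(occ, key=occ.get)
        if predominant != lowest:
            warnings.warn(
                f"most-occupied state is {predominant!r}, not the lowest-center "
                f"state {lowest!r}; zeroing to the lowest-center state", stacklevel=2)
        sel = [d for d in merged if d.state == lowest]
        if sel:
            offset = float(np.average([d.mean_level for d in sel],
                                      weights=[d.duration for d in sel]))
        merged = [d.with_(mean_level=d.mean_level - offset) for d in merged]

    shifted = StateModel(labels=model.labels,
                         centers_bp=model.centers_bp - offset,
                         boundaries_bp=model.boundaries_bp - offset,
                         oprime_label=model.oprime_label)
    return merged, offset, shifted


def occupancy_histogram(dwells: Sequence[Dwell], bin_bp: float = 0.5,
                        include_states: Optional[Sequence[str]] = None
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Lifetime-weighted occupation-probability histogram of dwell levels.

    Each dwell contributes its lifetime to the bin containing its mean
    level; the histogram is normalized to unit total mass.  Returns
    (bin_left_edges_bp, probability).
    """
    sel = [d for d in dwells
           if include_states is None or d.state in include_states]
    if not sel:
        raise ValueError("no dwells to histogram")
    levels = np.array([d.mean_level for d in sel])
    weights = np.array([d.duration for d in sel])
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total lifetime")
    lo = np.floor(levels.min() / bin_bp) * bin_bp
    hi = np.floor(levels.max() / bin_bp) * bin_bp + bin_bp
    edges = np.arange(lo, hi + 0.5 * bin_bp, bin_bp)
    hist, _ = np.histogram(levels, bins=edges, weights=weights)
    return edges[:-1], hist / total
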