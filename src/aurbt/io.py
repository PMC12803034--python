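"""Trace/table file formats, run configuration, and pipeline orchestration.

All on-disk formats are plain tab-separated text with metadata carried
in commented ``#`` header lines (JSON payload), so runs are diff-able
and reproducible: identical config and seeds give byte-identical
reports (no timestamps are written).

Units convention, stated once and used everywhere: angles in turns,
unwinding in bp (positive = unwound), energies in kBT, torques in
pN nm, rates in 1/s (cleavage rates in 1/min).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .cleavage import CleavageTimecourse, fit_monoexp
from .core import Dwell, OUParams
from .kinetics import derive_thermodynamics, equilibrium_landscape, transition_rates
from .segmentation import decimate, estimate_ou_params, segment_trace
from .states import assign_merge_zero, cluster_states, occupancy_histogram
from .synth import (StateSpec, TetherSpec, Trace,
                    simulate_ramp_trace, simulate_relaxed_trace)
from .torque import (bin_kinetics_by_twist, compute_torque, fit_tether_stiffness,
                     fit_twist_dependence, torque_to_unwinding, twist_density,
                     twist_landscape)

logger = logging.getLogger("aurbt")

_TRACE_MAGIC = "# aurbt-trace v1"
_TIME_TOL_S = 1e-9


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path: Union[str, Path]) -> None:
    """Write a trace as TSV with JSON metadata in commented header lines."""
    path = Path(path)
    meta = {
        "dt": trace.dt,
        "mode": trace.mode,
        "seed": trace.seed,
        "tether": dataclasses.asdict(trace.tether),
    }
    cols = ["time_s", "rotor_turns"]
    data = [trace.times, trace.rotor_turns]
    if trace.magnet_turns is not None:
        cols.append("magnet_turns")
        data.append(trace.magnet_turns)
    with open(path, "w") as fh:
        fh.write(_TRACE_MAGIC + "\n")
        fh.write("# meta " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, np.column_stack(data), fmt="%.17g", delimiter="\t")


def read_trace(path: Union[str, Path]) -> Trace:
    """Read a trace file; validates metadata and time-step uniformity."""
    path = Path(path)
    meta = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# meta "):
                meta = json.loads(line[len("# meta "):])
    if meta is None:
        raise ValueError(f"{path}: missing '# meta' header line")
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if "time_s" not in df.columns or "rotor_turns" not in df.columns:
        raise ValueError(f"{path}: missing required columns time_s/rotor_turns")
    t = df["time_s"].to_numpy()
    if t.size >= 2:
        steps = np.diff(t)
        if np.any(np.abs(steps - meta["dt"]) > _TIME_TOL_S):
            raise ValueError(f"{path}: non-uniform time step (tolerance {_TIME_TOL_S} s)")
    mode = meta["mode"]
    has_magnet = "magnet_turns" in df.columns
    if mode == "ramp" and not has_magnet:
        raise ValueError(f"{path}: ramp-mode trace lacks magnet_turns column")
    if mode == "relaxed" and has_magnet:
        raise ValueError(f"{path}: relaxed-mode trace has unexpected magnet_turns")
    tether = TetherSpec(**meta["tether"])
    return Trace(dt=meta["dt"], rotor_turns=df["rotor_turns"].to_numpy(),
                 mode=mode, tether=tether, seed=meta.get("seed"),
                 magnet_turns=df["magnet_turns"].to_numpy() if has_magnet else None)


# ---------------------------------------------------------------------------
# dwell / rate tables
# ---------------------------------------------------------------------------

def dwells_to_frame(dwells: Sequence[Dwell]) -> pd.DataFrame:
    return pd.DataFrame({
        "t_start_s": [d.t_start for d in dwells],
        "t_end_s": [d.t_end for d in dwells],
        "mean_level": [d.mean_level for d in dwells],
        "units": [d.units for d in dwells],
        "n_samples": [d.n_samples for d in dwells],
        "state": [d.state if d.state is not None else "" for d in dwells],
    })


def frame_to_dwells(df: pd.DataFrame) -> List[Dwell]:
    out = []
    for row in df.itertuples(index=False):
        state = row.state if isinstance(row.state, str) and row.state else None
        out.append(Dwell(t_start=row.t_start_s, t_end=row.t_end_s,
                         mean_level=row.mean_level, n_samples=int(row.n_samples),
                         units=row.units, state=state))
    return out


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {"mode", "out_dir", "seed"}
_MODE_KEYS = {
    "relaxed": {"trace_path"},
    "ramp": {"trace_path", "zero_offset_turns"},
    "cleavage": {"timecourse_path"},
    "simulate": {"trace_path"},
}


@dataclass
class RunConfig:
    """Flat key-value configuration of a pipeline run.

    Every stochastic step takes its seed from ``seed``; all defaulted
    analysis choices (penalty, bin width, linear region) are logged.
    """

    mode: str = ""
    out_dir: str = ""
    seed: Optional[int] = None
    trace_path: Optional[str] = None
    timecourse_path: Optional[str] = None
    # tether
    tether: Dict = field(default_factory=dict)
    # noise model: explicit parameters or baseline span (s) of the trace
    ou_tau_c_s: Optional[float] = None
    ou_sigma_turns: Optional[float] = None
    baseline_span_s: Optional[Tuple[float, float]] = None
    # segmentation
    penalty: Optional[float] = None
    min_dwell_samples: int = 5
    decimate_factor: int = 1
    # states
    state_centers_bp: Optional[List[float]] = None
    n_states: int = 3
    histogram_bin_bp: float = 0.5
    # torque-driven
    zero_offset_turns: float = 0.0
    twist_bin_width_turns: float = 0.5
    landscape_thetas: Tuple[float, ...] = (0.0, -5.0)
    # simulate mode
    sim: Dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        missing = [k for k in _REQUIRED_KEYS if not getattr(self, k, None)
                   and getattr(self, k, None) != 0]
        if self.mode and self.mode not in _MODE_KEYS:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode:
            for k in _MODE_KEYS[self.mode]:
                if getattr(self, k, None) is None:
                    missing.append(k)
        if missing:
            raise ValueError("config is missing required keys: "
                             + ", ".join(sorted(set(missing))))
        for key in ("trace_path", "timecourse_path"):
            p = getattr(self, key)
            if p is not None and self.mode != "simulate" and not Path(p).exists():
                raise ValueError(f"{key} does not resolve: {p}")

    def tether_spec(self) -> TetherSpec:
        return TetherSpec(**self.tether) if self.tether else TetherSpec()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _resolve_ou(cfg: RunConfig, trace: Trace) -> Tuple[OUParams, str]:
    if cfg.ou_tau_c_s is not None and cfg.ou_sigma_turns is not None:
        return OUParams(cfg.ou_tau_c_s, cfg.ou_sigma_turns), "config"
    if cfg.baseline_span_s is not None:
        lo, hi = cfg.baseline_span_s
        i0, i1 = int(lo / trace.dt), int(hi / trace.dt)
        ou = estimate_ou_params(trace.rotor_turns[i0:i1], trace.dt)
        return ou, f"baseline [{lo}, {hi}] s"
    raise ValueError("config must provide ou parameters or a baseline span")


def _landscape_json(ls) -> Dict:
    return {
        "theta_turns": ls.theta_turns,
        "well_labels": list(ls.well_labels),
        "well_x_bp": [round(v, 10) for v in ls.well_x_bp],
        "well_energy_kBT": [round(v, 10) for v in ls.well_energy_kBT],
        "barrier_x_bp": [round(v, 10) for v in ls.barrier_x_bp],
        "barrier_energy_kBT": [None if not math.isfinite(v) else round(v, 10)
                               for v in ls.barrier_energy_kBT],
        "truncated_after": ls.truncated_after,
    }


def _segment_and_label(cfg: RunConfig, series: np.ndarray, dt: float,
                       ou: OUParams, helicity: float, report: Dict,
                       units: str = "turns"):
    if cfg.decimate_factor > 1:
        series = decimate(series, cfg.decimate_factor)
        dt = dt * cfg.decimate_factor
    seg = segment_trace(series, ou, dt, penalty=cfg.penalty,
                        min_dwell_samples=cfg.min_dwell_samples)
    report["defaults"]["penalty"] = seg.penalty
    dwells = seg.dwells
    if units == "bp":
        dwells = [d.with_(units="bp") for d in dwells]
    if cfg.state_centers_bp is not None:
        model = cluster_states(dwells, initial_centers=cfg.state_centers_bp,
                               helicity=helicity)
    else:
        model = cluster_states(dwells, n_states=cfg.n_states, helicity=helicity)
    labeled, offset, model = assign_merge_zero(dwells, model, helicity=helicity)
    return seg, labeled, offset, model


def run_pipeline(config: Union[RunConfig, Dict, str, Path]) -> Dict:
    """Run the configured analysis end to end; returns the JSON report.

    Stage outputs (dwell table, rate table, thermodynamic table, state
    model, landscape) are written under ``out_dir`` alongside
    ``report.json`` and a run log.  A stage failure raises with the
    stage name; outputs of completed stages remain on disk.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: Dict = {
        "units": {"angles": "turns", "unwinding": "bp (positive = unwound)",
                  "energies": "kBT", "torque": "pN nm", "rates": "1/s",
                  "cleavage_rates": "1/min"},
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if v not in (None, {}, [])},
        "defaults": {},
    }
    stage = "setup"
    try:
        if config.mode == "simulate":
            stage = "simulate"
            _run_simulate(config, report)
        elif config.mode == "relaxed":
            stage = "relaxed analysis"
            _run_relaxed(config, out, report)
        elif config.mode == "ramp":
            stage = "ramp analysis"
            _run_ramp(config, out, report)
        elif config.mode == "cleavage":
            stage = "cleavage fits"
            _run_cleavage(config, out, report)
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _run_simulate(cfg: RunConfig, report: Dict) -> None:
    sim = dict(cfg.sim)
    kind = sim.pop("kind", "relaxed")
    tether = cfg.tether_spec()
    spec = StateSpec.default_cio(**sim.pop("rates", {}))
    ou = OUParams(sim.pop("tau_c_s", 0.005), sim.pop("sigma_turns", 0.05))
    duration = sim.pop("duration_s", 100.0)
    dt = sim.pop("dt_s", 1.0 / 5000.0)
    if kind == "relaxed":
        trace, truth = simulate_relaxed_trace(spec, ou, tether, duration, dt,
                                              seed=cfg.seed)
    else:
        trace, truth = simulate_ramp_trace(spec, ou, tether, sim.pop("ramp", None),
                                           duration, dt, seed=cfg.seed)
    write_trace(trace, cfg.trace_path)
    report["simulate"] = {"kind": kind, "n_samples": trace.n_samples,
                          "n_switches": int(len(truth.switch_times)),
                          "trace_path": str(cfg.trace_path)}
    logger.info("wrote %s trace with %d samples to %s", kind, trace.n_samples,
                cfg.trace_path)


def _rates_frame(rates) -> pd.DataFrame:
    return pd.DataFrame({
        "from_state": [r.pair[0] for r in rates],
        "to_state": [r.pair[1] for r in rates],
        "n": [r.n_transitions for r in rates],
        "occupancy_s": [r.occupancy_s for r in rates],
        "rate_s": [r.rate for r in rates],
        "se_s": [r.se for r in rates],
    })


def _run_relaxed(cfg: RunConfig, out: Path, report: Dict) -> None:
    trace = read_trace(cfg.trace_path)
    helicity = trace.tether.helicity
    ou, ou_src = _resolve_ou(cfg, trace)
    report["defaults"]["ou_source"] = ou_src
    report["ou"] = {"tau_c_s": ou.tau_c, "sigma_turns": ou.sigma}
    seg, labeled, offset, model = _segment_and_label(
        cfg, trace.rotor_turns, trace.dt, ou, helicity, report)
    write_table(dwells_to_frame(labeled), out / "dwells.tsv")
    with open(out / "state_model.json", "w") as fh:
        json.dump({"labels": list(model.labels),
                   "centers_bp": list(np.round(model.centers_bp, 10)),
                   "boundaries_bp": list(np.round(model.boundaries_bp, 10)),
                   "offset_bp": round(offset, 10)}, fh, indent=2, sort_keys=True)
    edges, probs = occupancy_histogram(labeled, bin_bp=cfg.histogram_bin_bp)
    write_table(pd.DataFrame({"bin_left_bp": edges, "probability": probs}),
                out / "occupancy_histogram.tsv")
    rates = transition_rates(labeled)
    write_table(_rates_frame(rates), out / "rates.tsv")
    thermo = derive_thermodynamics(rates)
    write_table(pd.DataFrame({
        "pair": [f"{t.pair[0]}-{t.pair[1]}" for t in thermo],
        "K": [t.K for t in thermo],
        "dG_kBT": [t.dG_kBT for t in thermo],
        "se_lnK": [t.se_lnK for t in thermo],
        "barrier_fwd_kBT": [t.barrier_kBT["fwd"] for t in thermo],
        "barrier_rev_kBT": [t.barrier_kBT["rev"] for t in thermo],
    }), out / "thermo.tsv")
    landscape = equilibrium_landscape(thermo, model)
    with open(out / "landscape.json", "w") as fh:
        json.dump(_landscape_json(landscape), fh, indent=2, sort_keys=True)
    report["states"] = {"labels": list(model.labels),
                        "centers_bp": [round(v, 6) for v in model.centers_bp],
                        "offset_bp": round(offset, 6),
                        "n_dwells": len(labeled)}
    report["rates"] = {f"{r.pair[0]}->{r.pair[1]}":
                       {"n": r.n_transitions, "occupancy_s": round(r.occupancy_s, 6),
                        "rate_s": round(r.rate, 6), "se_s": round(r.se, 6)}
                       for r in rates}
    report["thermo"] = {f"{t.pair[0]}-{t.pair[1]}":
                        {"K": round(t.K, 6), "dG_kBT": round(t.dG_kBT, 6),
                         "se_lnK": round(t.se_lnK, 6)} for t in thermo}
    report["landscape"] = _landscape_json(landscape)
    logger.info("relaxed analysis: %d dwells, %d rate pairs", len(labeled), len(rates))


def _run_ramp(cfg: RunConfig, out: Path, report: Dict) -> None:
    trace = read_trace(cfg.trace_path)
    tether = trace.tether
    helicity = tether.helicity
    torque = compute_torque(trace, cfg.zero_offset_turns)
    report["defaults"]["zero_offset_turns"] = cfg.zero_offset_turns

    # provisional unwinding with the nominal stiffness to find closed spans,
    # then re-fit kappa on those spans and redo the conversion
    provisional = torque_to_unwinding(torque, tether.kappa_rad, helicity)
    ou_rotor, ou_src = _resolve_ou(cfg, trace)
    report["defaults"]["ou_source"] = ou_src
    scale_bp = helicity * tether.kappa_t_rad / tether.kappa_rad
    ou_bp = OUParams(ou_rotor.tau_c, ou_rotor.sigma * scale_bp)
    seg, labeled, offset, model = _segment_and_label(
        cfg, provisional.unwound_bp, trace.dt, ou_bp, helicity, report, units="bp")
    # closed-state mask at full rate for the stiffness fit
    t_full = trace.times
    closed = np.zeros(t_full.size, dtype=bool)
    lowest = model.labels[0]
    for d in labeled:
        if d.state == lowest:
            closed[int(d.t_start / trace.dt):int(d.t_end / trace.dt)] = True
    kappa_rad, resid = fit_tether_stiffness(torque.torque_pNnm, torque.theta_turns,
                                            mask=closed)
    report["kappa_rad_pNnm"] = round(kappa_rad, 6)
    report["kappa_fit_intercept_pNnm"] = round(resid, 6)
    torque = torque_to_unwinding(torque, kappa_rad, helicity)
    write_table(dwells_to_frame(labeled), out / "dwells.tsv")

    theta_interp = lambda t: np.interp(t, t_full, torque.theta_turns)  # noqa: E731
    bins = bin_kinetics_by_twist(labeled, theta_interp,
                                 bin_width_turns=cfg.twist_bin_width_turns)
    report["defaults"]["twist_bin_width_turns"] = cfg.twist_bin_width_turns
    rows = []
    for b in bins:
        for r in b.rates:
            rows.append({"theta_center_turns": b.theta_center,
                         "from_state": r.pair[0], "to_state": r.pair[1],
                         "n": r.n_transitions, "occupancy_s": r.occupancy_s,
                         "rate_s": r.rate, "se_s": r.se})
    write_table(pd.DataFrame(rows), out / "twist_bins.tsv")
    fits = fit_twist_dependence(bins, tether)
    write_table(pd.DataFrame({
        "pair": [f"{f.pair[0]}-{f.pair[1]}" for f in fits],
        "slope_lnK": [f.slope_lnK for f in fits],
        "intercept_lnK": [f.intercept_lnK for f in fits],
        "delta_theta_turns": [f.delta_theta_turns for f in fits],
        "delta_theta_bp": [f.delta_theta_bp for f in fits],
        "dG0_kBT": [f.dG0_kBT for f in fits],
        "slope_lnk_fwd": [f.slope_lnk_fwd for f in fits],
        "barrier_fraction": [f.barrier_fraction for f in fits],
        "theta_min": [f.theta_range_lnk[0] if f.theta_range_lnk else None for f in fits],
        "theta_max": [f.theta_range_lnk[1] if f.theta_range_lnk else None for f in fits],
    }), out / "twist_fits.tsv")
    report["twist_fits"] = {
        f"{f.pair[0]}-{f.pair[1]}": {
            "slope_lnK": round(f.slope_lnK, 6),
            "delta_theta_turns": round(f.delta_theta_turns, 6),
            "dG0_kBT": round(f.dG0_kBT, 6),
            "barrier_fraction": None if f.barrier_fraction is None
            else round(f.barrier_fraction, 6),
            "lnk_region": f.theta_range_lnk,
        } for f in fits}
    report["twist_density_pct"] = {
        str(th): round(twist_density(th, tether), 6) for th in cfg.landscape_thetas}
    report["landscapes"] = [
        _landscape_json(twist_landscape(fits, model, theta=th))
        for th in cfg.landscape_thetas]
    with open(out / "landscapes.json", "w") as fh:
        json.dump(report["landscapes"], fh, indent=2, sort_keys=True)
    logger.info("ramp analysis: %d twist bins, %d fitted pairs", len(bins), len(fits))


def read_timecourse(path: Union[str, Path]) -> CleavageTimecourse:
    """Read a cleavage table with columns time_min, replicate, fraction."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"time_min", "replicate", "fraction"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    wide = df.pivot(index="replicate", columns="time_min", values="fraction")
    wide = wide.sort_index(axis=1)
    return CleavageTimecourse(times_min=wide.columns.to_numpy(dtype=float),
                              fraction=wide.to_numpy(),
                              replicate_ids=[str(r) for r in wide.index])


def write_timecourse(tc: CleavageTimecourse, path: Union[str, Path]) -> None:
    rows = []
    for r, rid in enumerate(tc.replicate_ids):
        for c, t in enumerate(tc.times_min):
            rows.append({"time_min": t, "replicate": rid,
                         "fraction": tc.fraction[r, c]})
    write_table(pd.DataFrame(rows), path)


def _run_cleavage(cfg: RunConfig, out: Path, report: Dict) -> None:
    tc = read_timecourse(cfg.timecourse_path)
    fit = fit_monoexp(tc)
    write_table(pd.DataFrame({
        "replicate": tc.replicate_ids,
        "A": fit.A, "kobs_per_min": fit.kobs, "converged": fit.converged,
    }), out / "cleavage_fits.tsv")
    report["cleavage"] = {
        "A_mean": None if math.isnan(fit.A_mean) else round(fit.A_mean, 6),
        "kobs_mean_per_min": None if math.isnan(fit.kobs_mean)
        else round(fit.kobs_mean, 6),
        "kobs_sd_per_min": None if fit.kobs_sd is None else round(fit.kobs_sd, 6),
        "n_reps": int(fit.converged.sum()),
        "per_replicate": {rid: {"A": None if math.isnan(a) else round(a, 6),
                                "kobs_per_min": None if math.isnan(k) else round(k, 6)}
                          for rid, a, k in zip(tc.replicate_ids, fit.A, fit.kobs)},
        "flags": fit.flags,
    }
    logger.info("cleavage fits: kobs mean %.4g 1/min over %d replicates",
                fit.kobs_mean, int(fit.converged.sum()))
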