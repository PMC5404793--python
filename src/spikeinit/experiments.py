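"""Config-driven experiment sweeps.

Each experiment takes a base model, sweeps one structural parameter, and
characterizes every condition with the same battery: rheobase, current-clamp
threshold (dV/dt = 5 mV/ms criterion), onset rapidness (maximum phase slope
of the first component, and the fixed-dV/dt measure at 20 mV/ms), the
tangent-based prediction from the distal axonal phase plot, the initiation
site, and -- when a clamp scan is enabled -- the voltage-clamp IV
discontinuity and peak transmitted current.

All runs are deterministic; a report row is regenerable from its archived
configuration.  Reports are plain columnar text with a JSON sidecar naming
the package version, a configuration hash and the solver settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    IVCurve,
    find_discontinuity,
    onset_rapidness,
    phase_plot,
    phase_slope_at,
    predict_onset_rapidness,
    spike_window,
)
from .cable import (
    CompartmentGraph,
    ModelConfig,
    build_model,
    cluster_channels,
    initiation_site,
    run_simulation,
)
from .lsa import field_snapshot
from .protocols import ClampProtocol, StimulusProtocol, detect_threshold, \
    find_rheobase, run_voltage_clamp
from .twocomp import TwoCompartmentParams, na_influx_charge, \
    simulate_two_compartment

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "characterize_model", "small_neuron_config"]

EXPERIMENTS = ("ri_sweep", "soma_size_sweep", "gna_sweep", "cluster_sweep",
               "two_compartment_suite", "small_neuron", "field_movie")


@dataclass
class ExperimentConfig:
    """One sweep: experiment name, base model, swept values, solver and
    clamp settings, optional output directory for report archiving."""

    name: str
    values: Sequence = field(default_factory=list)
    base: object | None = None          # ModelConfig or TwoCompartmentParams
    dt: float = 2e-3
    do_clamp: bool = True
    clamp_step_mv: float = 0.5
    clamp_halfspan_mv: float = 4.0      # scan threshold +- this span
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}")
        if self.name not in ("two_compartment_suite", "small_neuron",
                             "field_movie"):
            vals = list(self.values)
            if not vals:
                raise ValueError("swept values must be non-empty")
            if sorted(vals) != vals:
                raise ValueError("swept values must be sorted")


@dataclass
class ExperimentReport:
    table: pd.DataFrame
    config: ExperimentConfig
    artifacts: dict = field(default_factory=dict)


def small_neuron_config() -> ModelConfig:
    """Granule-cell-like preset: ~300 um^2 soma, thin 0.3 um axon."""
    d = math.sqrt(300.0 / math.pi)  # equal length and diameter
    return ModelConfig(soma_length=d, soma_diameter=d, axon_diameter=0.3)


def characterize_model(
    graph: CompartmentGraph,
    dt: float = 2e-3,
    do_clamp: bool = True,
    clamp_step_mv: float = 0.5,
    clamp_halfspan_mv: float = 4.0,
) -> dict:
    """Run the standard measurement battery on one model."""
    stride = max(int(round(0.01 / dt)), 1)
    rheo = find_rheobase(graph, dt=dt)
    stim = StimulusProtocol.step(1.5 * rheo, onset=1.0)
    res = run_simulation(graph, stim, duration=30.0, dt=dt,
                         record_stride=stride)
    v_s = res.v_soma
    thr = detect_threshold(res.t, v_s)
    win = spike_window(res.t, v_s)
    pp_s = phase_plot(res.t, v_s, window=win)
    rapid, info = onset_rapidness(pp_s, return_details=True)
    try:
        rapid20 = phase_slope_at(pp_s, 20.0)
    except ValueError:
        rapid20 = math.nan
    site = initiation_site(res)

    row = {
        "rheobase_pa": rheo,
        "threshold_cc_mv": thr,
        "onset_rapidness_per_ms": rapid,
        "phase_slope_at20_per_ms": rapid20,
        "n_components": info["n_components"],
        "initiation_site": site,
        "threshold_vc_mv": math.nan,
        "peak_clamp_current_na": math.nan,
        "tangent_prediction_per_ms": math.nan,
    }

    if "axon" in graph.sections and graph.sections["axon"][1] - graph.sections["axon"][0] > 0:
        v_a = res.v_axon_end
        try:
            pp_a = phase_plot(res.t, v_a, window=spike_window(res.t, v_a))
            row["tangent_prediction_per_ms"] = predict_onset_rapidness(pp_a, thr)
        except ValueError:
            pass

    if do_clamp and thr is not None:
        lo = thr - clamp_halfspan_mv
        n = int(round(2 * clamp_halfspan_mv / clamp_step_mv))
        clamp = ClampProtocol(
            commands=[lo + i * clamp_step_mv for i in range(n + 1)])
        cr = run_voltage_clamp(graph, clamp, dt=dt)
        iv = IVCurve.from_clamp(cr).annotate_discontinuity()
        row["threshold_vc_mv"] = (iv.discontinuity_voltage
                                  if iv.discontinuity_voltage is not None
                                  else math.nan)
        row["peak_clamp_current_na"] = float(np.max(np.abs(iv.peak_currents)))
    return row


def _graph_for(config: ExperimentConfig, value) -> CompartmentGraph:
    base = config.base or ModelConfig()
    if config.name == "ri_sweep":
        return build_model(dataclasses.replace(base, r_i=float(value)))
    if config.name == "soma_size_sweep":
        d = math.sqrt(float(value) / math.pi)  # area = pi d^2 with L = d
        return build_model(dataclasses.replace(
            base, soma_length=d, soma_diameter=d))
    if config.name == "gna_sweep":
        f = float(value)
        return build_model(dataclasses.replace(
            base,
            na_density_axon=base.na_density_axon * f,
            na_density_soma=base.na_density_soma * f))
    if config.name == "cluster_sweep":
        cfg = dataclasses.replace(base, axon_segments=10)
        return cluster_channels(build_model(cfg), int(value))
    if config.name == "small_neuron":
        return build_model(base if config.base is not None
                           else small_neuron_config())
    raise ValueError(config.name)


def _config_hash(config: ExperimentConfig) -> str:
    base = config.base
    base_repr = dataclasses.asdict(base) if dataclasses.is_dataclass(base) else str(base)
    blob = json.dumps({
        "name": config.name, "values": list(config.values),
        "base": base_repr, "dt": config.dt,
        "clamp_step_mv": config.clamp_step_mv,
        "clamp_halfspan_mv": config.clamp_halfspan_mv,
    }, sort_keys=True, default=str)
    return hashlib.md5(blob.encode()).hexdigest()


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run a sweep and return its report table.

    A failure in one condition is recorded in that row's ``error`` column
    and the sweep continues.
    """
    artifacts: dict = {}
    rows = []

    if config.name == "two_compartment_suite":
        params = config.base or TwoCompartmentParams()
        rheo = find_rheobase(params, dt=min(config.dt, 5e-3))
        stim = StimulusProtocol.step(1.5 * rheo, onset=1.0)
        res = simulate_two_compartment(params, stim, duration=30.0,
                                       dt=min(config.dt, 5e-3),
                                       record_stride=1)
        win = spike_window(res.t, res.v_soma)
        pp_s = phase_plot(res.t, res.v_soma, window=win)
        rapid, info = onset_rapidness(pp_s, return_details=True)
        q_a = na_influx_charge(res, ("axon", 0), window=win)
        q_s = na_influx_charge(res, "soma", window=win)
        rows.append({
            "value": "default", "rheobase_pa": rheo,
            "threshold_cc_mv": detect_threshold(res.t, res.v_soma),
            "onset_rapidness_per_ms": rapid,
            "n_components": info["n_components"],
            "na_charge_ais_pc": q_a, "na_charge_soma_pc": q_s,
            "na_influx_excess_pct": 100.0 * (q_a / q_s - 1.0),
        })
        artifacts["sim_result"] = res
    elif config.name == "field_movie":
        base = config.base or ModelConfig()
        graph = build_model(base)
        rheo = find_rheobase(graph, dt=config.dt)
        stim = StimulusProtocol.step(1.5 * rheo, onset=1.0)
        res = run_simulation(graph, stim, duration=25.0, dt=config.dt,
                             record_stride=max(int(round(0.01 / config.dt)), 1))
        frames = []
        for t in config.values:
            fg = field_snapshot(res, float(t))
            frames.append(fg)
            rows.append({"value": float(t),
                         "phi_min_uv": float(fg.phi.min()),
                         "phi_max_uv": float(fg.phi.max())})
        artifacts["frames"] = frames
        artifacts["sim_result"] = res
    else:
        values = config.values if config.name not in ("small_neuron",) \
            else (config.values or ["preset"])
        for value in values:
            row = {"value": value}
            try:
                graph = _graph_for(config, value)
                row.update(characterize_model(
                    graph, dt=config.dt, do_clamp=config.do_clamp,
                    clamp_step_mv=config.clamp_step_mv,
                    clamp_halfspan_mv=config.clamp_halfspan_mv))
            except Exception as exc:  # noqa: BLE001 - per-row error policy
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)

    table = pd.DataFrame(rows)
    report = ExperimentReport(table=table, config=config, artifacts=artifacts)
    if config.out_dir is not None:
        os.makedirs(config.out_dir, exist_ok=True)
        table.to_csv(os.path.join(config.out_dir, f"{config.name}.tsv"),
                     sep="\t", index=False, float_format="%.6g")
        meta = {
            "experiment": config.name,
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "dt_ms": config.dt,
            "clamp_step_mv": config.clamp_step_mv,
        }
        with open(os.path.join(config.out_dir, f"{config.name}.meta.json"),
                  "w") as fh:
            json.dump(meta, fh, indent=2)
    return report
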