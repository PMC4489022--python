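"""File formats, configuration, and the end-to-end pipeline runner.

All tabular artifacts are plain delimited text with unit-bearing
headers (``time_s,position_um``; ``cell_id,time_s``), universally
parseable; configuration is YAML.  A :class:`RunManifest` records the
config snapshot, per-stage seeds, file digests and timings so a run
can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from retinotrack import __version__
from retinotrack.retina import SpikeTrainSet
from retinotrack.trajectory import Trajectory

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_trajectory",
    "write_trajectory",
    "write_filters",
    "read_filters",
    "load_config",
    "RunManifest",
    "run_pipeline",
    "DEFAULT_CONFIG",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# spike trains
# --------------------------------------------------------------------------

def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    """Delimited text ``cell_id,time_s``, one row per spike."""
    rows = [(cid, t) for cid, times in zip(spikes.ids, spikes.cells)
            for t in times]
    df = pd.DataFrame(rows, columns=["cell_id", "time_s"])
    header = f"# duration_s={spikes.duration!r} n_cells={spikes.n_cells}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_spikes(path: str | Path,
                duration: float | None = None) -> SpikeTrainSet:
    """Read ``cell_id,time_s`` text; times are sorted per cell on read
    (logged when input was out of order).  An empty file is an error."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = float(v)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no spikes in file")
    if not {"cell_id", "time_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns cell_id,time_s")
    if duration is None:
        duration = meta.get("duration_s", float(df.time_s.max()) + 1e-6)
    ids = sorted(df.cell_id.unique())
    cells = []
    for cid in ids:
        t = df.loc[df.cell_id == cid, "time_s"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            log.info("cell %s spike times out of order in %s; sorted", cid, path)
            t = np.sort(t)
        cells.append(t)
    return SpikeTrainSet(duration=float(duration), cells=cells,
                         ids=[int(i) for i in ids])


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": traj.t, "position_um": traj.x})
    with open(path, "w") as fh:
        fh.write(f"# t0={traj.t0!r} dt={traj.dt!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty trajectory file")
    t = df.time_s.to_numpy(float)
    dt = float(np.median(np.diff(t)))
    return Trajectory(t0=float(t[0]), dt=dt, x=df.position_um.to_numpy(float))


# --------------------------------------------------------------------------
# decoder filters
# --------------------------------------------------------------------------

def write_filters(filters, path: str | Path) -> None:
    """``cell_id,lag_s,weight_um`` rows plus the constant in the header."""
    rows = [(cid, lag, w)
            for cid, k in filters.filters.items()
            for lag, w in zip(filters.grid.lags, k)]
    df = pd.DataFrame(rows, columns=["cell_id", "lag_s", "weight_um"])
    with open(path, "w") as fh:
        fh.write(f"# constant_um={filters.constant!r} "
                 f"bin_s={filters.grid.bin!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_filters(path: str | Path):
    from retinotrack.decoding import DecoderFilters, LagGrid

    with open(path) as fh:
        first = fh.readline()
    meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    bin_s = float(meta["bin_s"])
    lags = np.sort(df.lag_s.unique())
    grid = LagGrid(bin=bin_s, lag_min=float(lags[0]), lag_max=float(lags[-1]),
                   causal=lags[-1] <= 1e-12)
    filt = {}
    for cid, sub in df.groupby("cell_id"):
        filt[int(cid)] = sub.sort_values("lag_s").weight_um.to_numpy(float)
    return DecoderFilters(filters=filt, constant=float(meta["constant_um"]),
                          grid=grid)


# --------------------------------------------------------------------------
# configuration and pipeline
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "duration_s": 300.0,
    "n_cells": 40,
    "span_um": 1500.0,
    "ensemble": "spring-ou",       # or "lowpass-white"
    "causal": False,
    "acausal": True,
    "l1": False,
    "l1_threshold": 0.85,
    "neural_image": True,
    "spectra": True,
    "info": True,
    "info_subset_size": 10,
    "characterize": False,
}


def load_config(path: str | Path) -> dict:
    """YAML config merged over defaults; unknown keys are an error."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    results: dict[str, float] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)
    version: str = __version__

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute simulate -> encode -> decode (-> L1) -> neural image ->
    spectra -> information on one synthetic recording.

    Every stochastic stage draws its seed deterministically from the
    master seed; all outputs are written as delimited text under
    ``out_dir`` together with the manifest.  A stage failure aborts the
    run but the manifest of completed stages is still written.
    """
    from retinotrack.trajectory import (BarGeometry, LowpassWhiteParams,
                                        simulate_lowpass_white,
                                        simulate_spring_ou)
    from retinotrack.retina import (PopulationConfig, encode,
                                    make_population,
                                    salamander_like_trajectory_params)
    from retinotrack.decoding import LagGrid, LinearDecoder
    from retinotrack.neural_image import (build_image, decode_peak,
                                          sparse_estimate_cc)
    from retinotrack.spectra import error_psd
    from retinotrack.information import signal_info_rate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(int(config["seed"]))
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(
                       ["trajectory", "population", "encode", "subsets"],
                       ss.spawn(4))}
    manifest = RunManifest(config=dict(config), seeds=stage_seeds)

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception:
                manifest.save(out / "manifest.yaml")
                raise
            manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
            manifest.completed.append(name)
        return wrap

    state: dict = {}

    @_stage("simulate")
    def _():
        dur = float(config["duration_s"])
        if config["ensemble"] == "spring-ou":
            p = salamander_like_trajectory_params(dur, stage_seeds["trajectory"])
            traj = simulate_spring_ou(p).resample(1 / 60)
        elif config["ensemble"] == "lowpass-white":
            p = LowpassWhiteParams(duration=dur, seed=stage_seeds["trajectory"])
            traj = simulate_lowpass_white(p)
        else:
            raise ValueError(f"unknown ensemble {config['ensemble']!r}")
        state["traj"] = traj
        write_trajectory(traj, out / "trajectory.csv")

    @_stage("encode")
    def _():
        cells = make_population(PopulationConfig(
            n_cells=int(config["n_cells"]), span=float(config["span_um"]),
            seed=stage_seeds["population"]))
        spikes = encode(state["traj"], BarGeometry(), cells,
                        seed=stage_seeds["encode"])
        state["cells"], state["spikes"] = cells, spikes
        write_spikes(spikes, out / "spikes.csv")
        rows = [dict(cell_id=c.id, center_um=c.center, center_sd_um=c.center_sd,
                     polarity=c.polarity, label=c.label) for c in cells]
        pd.DataFrame(rows).to_csv(out / "cells_truth.csv", index=False)

    @_stage("decode")
    def _():
        spikes, traj = state["spikes"], state["traj"]
        for name, causal in (("acausal", False), ("causal", True)):
            if not config[name]:
                continue
            model = LinearDecoder(spikes, traj, grid=LagGrid(causal=causal))
            res = model.fit()
            state[f"model_{name}"] = model
            state[f"res_{name}"] = res
            manifest.results[f"cc_test_{name}"] = round(res.cc_test, 4)
            write_filters(res.filters, out / f"filters_{name}.csv")
            write_trajectory(res.prediction, out / f"prediction_{name}.csv")
        if not ("res_acausal" in state or "res_causal" in state):
            raise ValueError("at least one of acausal/causal must be enabled")

    @_stage("l1")
    def _():
        if not config["l1"]:
            return
        from retinotrack.regularized import disjoint_subsets
        model = state.get("model_acausal") or state["model_causal"]
        dec = disjoint_subsets(model, threshold=float(config["l1_threshold"]))
        dec.to_frame().to_csv(out / "disjoint_subsets.csv", index=False)
        manifest.results["n_disjoint_subsets"] = dec.n_subsets

    @_stage("neural_image")
    def _():
        if not config["neural_image"]:
            return
        spikes, traj, cells = state["spikes"], state["traj"], state["cells"]
        centers = np.array([c.center for c in cells])
        lo = min(traj.x.min(), centers.min()) - 50
        hi = max(traj.x.max(), centers.max()) + 50
        grid = np.arange(lo, hi, 10.0)
        img = build_image(spikes, np.array([c.center for c in cells]), grid)
        bins, est = decode_peak(img)
        manifest.results["cc_neural_image_peak"] = round(
            sparse_estimate_cc(bins, est, traj.x), 4)

    @_stage("spectra")
    def _():
        if not config["spectra"]:
            return
        res = state.get("res_acausal") or state["res_causal"]
        model = state.get("model_acausal") or state["model_causal"]
        f, psd = error_psd(res._pred, model._y, fs=1 / model.grid.bin)
        pd.DataFrame({"freq_hz": f, "error_psd_um2_per_hz": psd}).to_csv(
            out / "error_psd.csv", index=False)
        manifest.results["rmse_um"] = round(float(np.sqrt(np.mean(res.resid**2))), 2)

    @_stage("info")
    def _():
        if not config["info"]:
            return
        model = state.get("model_acausal") or state["model_causal"]
        res = state.get("res_acausal") or state["res_causal"]
        te = ~model._is_train
        est = signal_info_rate(model._y[te], res._pred[te],
                               fs=1 / model.grid.bin)
        manifest.results["info_rate_bits_per_s"] = round(est.info_rate, 3)

    for f in (out / "trajectory.csv", out / "spikes.csv"):
        if f.exists():
            manifest.digests[f.name] = _digest(f)
    manifest.save(out / "manifest.yaml")
    return manifest
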