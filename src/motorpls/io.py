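"""Reading and writing the pipeline's on-disk formats.

Time series and spike tables travel as delimited text (one header line);
fitted oscillator parameters as JSON; and the shared results container --
which lets pipeline stages be rerun independently -- as an HDF5 file with
one group per stage (``raw``, ``spikes``, ``signals``, ``ensemble``,
``pls``, ``significance``, ``deciles``). Tabular outputs (PRESS tables,
per-decile errors) are exported as CSV next to the container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ensemble import DecilePartition, MotorSignals, SpikeTable, WaveformEnsemble
from .exceptions import InputError
from .pls import FeatureSignificance, PLSModel
from .torquemeter import OscillatorModel

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_spike_table",
    "write_spike_table",
    "load_oscillator",
    "save_oscillator",
    "ResultsContainer",
]


def read_timeseries(path) -> pd.DataFrame:
    """Delimited time series: one header line, first column time (s)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise InputError(f"{path}: need a time column plus at least one channel")
    return df


def write_timeseries(path, time: np.ndarray, channels: dict[str, np.ndarray]):
    df = pd.DataFrame({"time": np.asarray(time)})
    for name, values in channels.items():
        df[name] = np.asarray(values)
    df.to_csv(path, index=False)


def read_spike_table(path) -> SpikeTable:
    """Two-column delimited text: channel label, spike time in seconds."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"channel", "time_s"}.issubset(df.columns):
        raise InputError(f"{path}: expected columns 'channel' and 'time_s'")
    return SpikeTable(
        {str(ch): np.sort(sub["time_s"].to_numpy()) for ch, sub in df.groupby("channel")}
    )


def write_spike_table(path, spikes: SpikeTable):
    rows = [
        {"channel": label, "time_s": t}
        for label in spikes.labels
        for t in spikes[label]
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_oscillator(path, model: OscillatorModel):
    Path(path).write_text(model.to_json())


def load_oscillator(path) -> OscillatorModel:
    return OscillatorModel.from_json(Path(path).read_text())


def _write_group(h5: h5py.File, name: str, fields: dict):
    if name in h5:
        del h5[name]
    grp = h5.create_group(name)
    for key, value in fields.items():
        if value is None:
            continue
        if isinstance(value, (str, int, float, bool, np.integer, np.floating)):
            grp.attrs[key] = value
        elif isinstance(value, (tuple, list)) and all(isinstance(v, str) for v in value):
            grp.attrs[key] = json.dumps(list(value))
        else:
            grp.create_dataset(key, data=np.asarray(value))


class ResultsContainer:
    """Stage-by-stage HDF5 container for one recording's analysis."""

    def __init__(self, path):
        self.path = Path(path)

    def _open(self, mode):
        return h5py.File(self.path, mode)

    # -- raw signals -------------------------------------------------------
    def save_raw(self, torque=None, angle=None, sample_rate=10_000.0):
        with self._open("a") as h5:
            _write_group(
                h5, "raw",
                {"torque": torque, "angle": angle, "sample_rate": sample_rate},
            )

    def load_raw(self):
        with self._open("r") as h5:
            grp = h5["raw"]
            return {
                "torque": grp["torque"][...] if "torque" in grp else None,
                "angle": grp["angle"][...] if "angle" in grp else None,
                "sample_rate": float(grp.attrs["sample_rate"]),
            }

    # -- spikes ------------------------------------------------------------
    def save_spikes(self, spikes: SpikeTable):
        with self._open("a") as h5:
            _write_group(h5, "spikes", {lab: spikes[lab] for lab in spikes.labels})

    def load_spikes(self) -> SpikeTable:
        with self._open("r") as h5:
            return SpikeTable({k: h5["spikes"][k][...] for k in h5["spikes"]})

    # -- aligned matrices --------------------------------------------------
    def save_ensemble(self, ensemble: WaveformEnsemble):
        with self._open("a") as h5:
            _write_group(
                h5, "ensemble",
                {
                    "M": ensemble.M, "sta": ensemble.sta, "s": ensemble.s,
                    "mean_torque": ensemble.mean_torque, "onsets": ensemble.onsets,
                    "mode": ensemble.mode, "window_ms": ensemble.window_ms,
                    "sample_rate": ensemble.sample_rate,
                    "cycle_index": ensemble.cycle_index,
                    "n_dropped": ensemble.n_dropped,
                },
            )

    def load_ensemble(self) -> WaveformEnsemble:
        with self._open("r") as h5:
            g = h5["ensemble"]
            return WaveformEnsemble(
                M=g["M"][...], sta=g["sta"][...], s=float(g.attrs["s"]),
                mean_torque=g["mean_torque"][...], onsets=g["onsets"][...],
                mode=str(g.attrs["mode"]), window_ms=float(g.attrs["window_ms"]),
                sample_rate=float(g.attrs["sample_rate"]),
                cycle_index=g["cycle_index"][...],
                n_dropped=int(g.attrs["n_dropped"]),
            )

    def save_signals(self, signals: MotorSignals):
        with self._open("a") as h5:
            _write_group(
                h5, "signals",
                {
                    "U": signals.U, "raw": signals.raw, "labels": signals.labels,
                    "center": signals.center, "scale": signals.scale,
                    "cycle_index": signals.cycle_index,
                },
            )

    def load_signals(self) -> MotorSignals:
        with self._open("r") as h5:
            g = h5["signals"]
            return MotorSignals(
                U=g["U"][...], raw=g["raw"][...],
                labels=tuple(json.loads(g.attrs["labels"])),
                center=g["center"][...], scale=g["scale"][...],
                cycle_index=g["cycle_index"][...],
            )

    # -- decomposition -----------------------------------------------------
    def save_pls(self, model: PLSModel):
        with self._open("a") as h5:
            _write_group(
                h5, "pls",
                {
                    "R": model.R, "C": model.C, "P": model.P, "Q": model.Q,
                    "K": model.K, "D": model.D, "B": model.B, "V": model.V,
                    "score_norms": model.score_norms,
                    "n_components": model.n_components,
                    "n_requested": model.n_requested,
                    "deflation": model.deflation,
                },
            )

    def load_pls(self) -> PLSModel:
        with self._open("r") as h5:
            g = h5["pls"]
            return PLSModel(
                R=g["R"][...], C=g["C"][...], P=g["P"][...], Q=g["Q"][...],
                K=g["K"][...], D=g["D"][...], B=g["B"][...], V=g["V"][...],
                score_norms=g["score_norms"][...],
                n_components=int(g.attrs["n_components"]),
                n_requested=int(g.attrs["n_requested"]),
                deflation=str(g.attrs["deflation"]),
            )

    def save_significance(self, sig: FeatureSignificance):
        with self._open("a") as h5:
            _write_group(
                h5, "significance",
                {
                    "observed": sig.observed, "threshold": sig.threshold,
                    "flags": sig.flags.astype(np.uint8), "null_max": sig.null_max,
                    "quantile": sig.quantile, "n_resamples": sig.n_resamples,
                    "per_feature": sig.per_feature,
                    "seed": -1 if sig.seed is None else sig.seed,
                },
            )

    def load_significance(self) -> FeatureSignificance:
        with self._open("r") as h5:
            g = h5["significance"]
            seed = int(g.attrs["seed"])
            return FeatureSignificance(
                observed=g["observed"][...], threshold=g["threshold"][...],
                flags=g["flags"][...].astype(bool), null_max=g["null_max"][...],
                quantile=float(g.attrs["quantile"]),
                n_resamples=int(g.attrs["n_resamples"]),
                per_feature=bool(g.attrs["per_feature"]),
                seed=None if seed < 0 else seed,
            )

    def save_deciles(self, partition: DecilePartition):
        with self._open("a") as h5:
            _write_group(
                h5, "deciles",
                {
                    "labels": partition.labels,
                    "group_means": partition.group_means,
                    "group_mean_torque": partition.group_mean_torque,
                    "n_groups": partition.n_groups,
                },
            )

    def load_deciles(self) -> DecilePartition:
        with self._open("r") as h5:
            g = h5["deciles"]
            return DecilePartition(
                labels=g["labels"][...], group_means=g["group_means"][...],
                group_mean_torque=g["group_mean_torque"][...],
                n_groups=int(g.attrs["n_groups"]),
            )

    def has(self, group: str) -> bool:
        if not self.path.exists():
            return False
        with self._open("r") as h5:
            return group in h5
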