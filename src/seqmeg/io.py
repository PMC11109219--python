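"""On-disk formats: HDF5 epoch containers, CSV tables, YAML/JSON configs.

Epochs live in an HDF5 file (datasets ``data``, ``labels``, ``times``,
``channel_types``; attributes ``sfreq``, ``baseline``, ``time_zero``) with
an optional JSON sidecar describing the sequence design.  Behavioural
tables are CSV with columns subject, condition, n_correct, mean_rt_ms.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import Leadfield, SensorEpochs, SequenceDesign, SourceGrid


def write_epochs(path: str | Path, epochs: SensorEpochs,
                 design: SequenceDesign | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels",
                         data=np.asarray(epochs.labels, dtype="S"))
        f.create_dataset("times", data=epochs.times_s())
        f.create_dataset("channel_types",
                         data=np.asarray(epochs.channel_types, dtype="S"))
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["baseline"] = epochs.baseline_window
        f.attrs["time_zero"] = epochs.time_zero
    if design is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(design_to_dict(design), indent=1))


def read_epochs(path: str | Path) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        return SensorEpochs(
            data=f["data"][()],
            labels=np.array([s.decode() for s in f["labels"][()]],
                            dtype=object),
            sfreq=float(f.attrs["sfreq"]),
            baseline_window=tuple(int(v) for v in f.attrs["baseline"]),
            channel_types=np.array(
                [s.decode() for s in f["channel_types"][()]], dtype=object),
            time_zero=int(f.attrs["time_zero"]),
        )


def design_to_dict(design: SequenceDesign) -> dict:
    return {
        "n_trials_per_condition": design.n_trials_per_condition,
        "conditions": list(design.conditions),
        "tone_onsets_ms": design.tone_onsets_ms.tolist(),
        "tone_duration_ms": design.tone_duration_ms,
        "epoch_ms": design.epoch_ms,
        "baseline_ms": design.baseline_ms,
        "sfreq": design.sfreq,
        "pitch_sequences": design.pitch_sequences.tolist(),
        "varied_from": design.varied_from.tolist(),
        "variation_strategy": list(design.variation_strategy),
    }


def design_from_dict(d: dict) -> SequenceDesign:
    return SequenceDesign(
        n_trials_per_condition=int(d["n_trials_per_condition"]),
        conditions=np.array(d["conditions"], dtype=object),
        tone_onsets_ms=np.asarray(d["tone_onsets_ms"], dtype=float),
        tone_duration_ms=float(d["tone_duration_ms"]),
        epoch_ms=float(d["epoch_ms"]),
        baseline_ms=float(d["baseline_ms"]),
        sfreq=float(d["sfreq"]),
        pitch_sequences=np.asarray(d["pitch_sequences"], dtype=int),
        varied_from=np.asarray(d["varied_from"], dtype=int),
        variation_strategy=np.array(d["variation_strategy"], dtype=object),
    )


def write_leadfield(path: str | Path, lf: Leadfield) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        if lf.reduced is not None:
            f.create_dataset("reduced", data=lf.reduced)
        f.create_dataset("coords", data=lf.grid.coords)
        f.create_dataset("parcel_label",
                         data=np.asarray(lf.grid.parcel_label, dtype="S"))
        f.attrs["spacing_mm"] = lf.grid.spacing_mm


def read_leadfield(path: str | Path) -> Leadfield:
    with h5py.File(path, "r") as f:
        grid = SourceGrid(
            coords=f["coords"][()],
            spacing_mm=float(f.attrs["spacing_mm"]),
            parcel_label=np.array(
                [s.decode() for s in f["parcel_label"][()]], dtype=object),
        )
        reduced = f["reduced"][()] if "reduced" in f else None
        return Leadfield(gain=f["gain"][()], grid=grid, reduced=reduced)


def write_behavior(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)
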