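"""Container I/O and run configuration.

Epoch sets travel in a small hierarchical HDF5 schema::

    /data                (n_trials, n_channels, n_samples) float64, microvolt
    /times               (n_samples,) float64, ms, t=0 at pre-cue onset
    /trials/<column>     per-trial labels and pulse times (strings/floats)
    attrs: fs (Hz), ch_names (list of str), schema ("entraineeg-epochs-1")

Trial schedules are plain CSV (block, trial, rhythmicity, stimulation,
target_side, p1..p4).  Run configurations are YAML with a mandatory
seed; a run is reproducible from (config, seed) alone.  Continuous real
recordings can be imported from BrainVision triplets (.vhdr/.vmrk/.eeg)
via MNE; a minimal triplet writer is provided so round-trips can be
exercised without external data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import EpochSet, RawRecording
from .synth import OscillatorModel

SCHEMA = "entraineeg-epochs-1"


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to the HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["ch_names"] = list(epochs.ch_names)
        f.attrs["schema"] = SCHEMA
        g = f.create_group("trials")
        for col in epochs.trial_info.columns:
            vals = epochs.trial_info[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype(str)
                g.create_dataset(col, data=np.char.encode(vals, "utf-8"))
            else:
                g.create_dataset(col, data=vals)


def read_epochs(path: str | Path) -> EpochSet:
    """Read the HDF5 container back; raises a schema error naming any missing field."""
    with h5py.File(path, "r") as f:
        for key in ("data", "times", "trials"):
            if key not in f:
                raise ValueError(f"epoch container missing required field '{key}'")
        for attr in ("fs", "ch_names", "schema"):
            if attr not in f.attrs:
                raise ValueError(f"epoch container missing required attribute '{attr}'")
        if f.attrs["schema"] != SCHEMA:
            raise ValueError(f"unknown schema '{f.attrs['schema']}'")
        cols = {}
        for col, ds in f["trials"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                vals = np.char.decode(vals, "utf-8")
            cols[col] = vals
        return EpochSet(
            f["data"][()],
            f["times"][()],
            float(f.attrs["fs"]),
            tuple(str(c) for c in f.attrs["ch_names"]),
            pd.DataFrame(cols),
        )


def write_schedule(schedule: pd.DataFrame, path: str | Path) -> None:
    schedule.to_csv(path, index=False)


def read_schedule(path: str | Path) -> pd.DataFrame:
    sched = pd.read_csv(path)
    required = {"block", "trial", "rhythmicity", "stimulation", "p1", "p2", "p3", "p4"}
    missing = required - set(sched.columns)
    if missing:
        raise ValueError(f"schedule missing columns: {sorted(missing)}")
    return sched


# ------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Fully serializable description of one simulation + analysis run."""

    seed: int
    n_participants: int = 2
    n_blocks: int = 2
    trials_per_block: int = 32
    montage: str = "reduced8"  # "reduced8" | "full63"
    oscillator: dict = field(default_factory=dict)  # OscillatorModel overrides
    freq: float = 10.0
    n_perm: int = 1000
    n_bins: int = 6
    stimulus_onset_ms: float = 530.0
    out_dir: str = "results"

    def channels(self) -> tuple[str, ...]:
        from .montage import CHANNELS_8, CHANNELS_63

        return CHANNELS_8 if self.montage == "reduced8" else CHANNELS_63

    def model(self, **overrides) -> OscillatorModel:
        return OscillatorModel(**{**self.oscillator, **overrides})


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "seed" not in raw:
        raise ValueError("config must set a seed; runs are reproducible "
                         "from (config, seed) alone")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(config), f, sort_keys=False)


# ------------------------------------------------------------ BrainVision


def read_brainvision(vhdr_path: str | Path) -> RawRecording:
    """Import a continuous BrainVision recording as a :class:`RawRecording`."""
    import mne

    mne.set_log_level("ERROR")
    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True)
    data_uv = raw.get_data() * 1e6
    times_ms = raw.times * 1000.0
    return RawRecording(data_uv, times_ms, float(raw.info["sfreq"]),
                        tuple(raw.ch_names))


def write_brainvision(
    data_uv: np.ndarray,
    fs: float,
    ch_names: tuple[str, ...],
    vhdr_path: str | Path,
) -> None:
    """Write a minimal BrainVision triplet (IEEE float32, multiplexed).

    Intended for generating small synthetic fixtures and round-trip
    checks; real exports should use a dedicated writer.
    """
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.with_suffix("")
    n_ch, _ = data_uv.shape
    if len(ch_names) != n_ch:
        raise ValueError("ch_names must match the channel axis")
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={stem.name}.eeg",
        f"MarkerFile={stem.name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    header += [
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(ch_names)
    ]
    vhdr_path.write_text("\n".join(header) + "\n", encoding="utf-8")
    marker = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={stem.name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    stem.with_suffix(".vmrk").write_text("\n".join(marker) + "\n", encoding="utf-8")
    data_uv.astype("<f4").T.tofile(stem.with_suffix(".eeg"))
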