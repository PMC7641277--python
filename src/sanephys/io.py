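"""Readers and writers for the repository's file dialects.

Traces: 2-column delimited text (time_s, value) or HDF5 datasets with
attributes {sampling_rate_hz, units}. Beat tables: headered delimited text
(beat, t_s, rr_ms[, sbp_mmhg]). Premature-stimulation tables: headered CSV.
Frame stacks: HDF5 3-D datasets with attributes {pitch_um, frame_rate_hz}.
Segmentations: BED-like tab-separated interval tables (start_s, end_s, mode).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import BeatSeries, EpisodeSegmentation, FrameStack, UniformTrace


def write_trace(path, trace: UniformTrace) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("trace", data=trace.values)
            d.attrs["sampling_rate_hz"] = trace.sampling_rate
            d.attrs["units"] = trace.units
            d.attrs["t0_s"] = trace.t0
    else:
        np.savetxt(
            path,
            np.column_stack([trace.times, trace.values]),
            delimiter="\t",
            header="time_s\tvalue",
            comments="",
        )


def read_trace(path) -> UniformTrace:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            d = f["trace"]
            return UniformTrace(
                d[...],
                float(d.attrs["sampling_rate_hz"]),
                t0=float(d.attrs.get("t0_s", 0.0)),
                units=str(d.attrs.get("units", "mV")),
            )
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace file is not uniformly sampled")
    fs = 1.0 / dt[0] if dt.size else 1.0
    return UniformTrace(v, fs, t0=float(t[0]))


def write_beats(path, beats: BeatSeries) -> None:
    beats.to_frame().to_csv(path, index=False)


def read_beats(path) -> BeatSeries:
    df = pd.read_csv(path)
    sbp = df["sbp_mmhg"].to_numpy() if "sbp_mmhg" in df.columns else None
    return BeatSeries(
        rr_ms=df["rr_ms"].to_numpy(),
        t_s=df["t_s"].to_numpy(),
        sbp_mmhg=sbp,
    )


def write_stim_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_stim_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stack(path, stack: FrameStack) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=stack.frames)
        d.attrs["pitch_um"] = stack.pitch_um
        d.attrs["frame_rate_hz"] = stack.frame_rate


def read_stack(path) -> FrameStack:
    with h5py.File(path, "r") as f:
        d = f["frames"]
        return FrameStack(
            d[...],
            pitch_um=float(d.attrs["pitch_um"]),
            frame_rate=float(d.attrs["frame_rate_hz"]),
        )


def write_segmentation(path, seg: EpisodeSegmentation) -> None:
    seg.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_segmentation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["start_s", "end_s", "mode"])
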