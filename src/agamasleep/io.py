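"""Recording container I/O.

HDF5 layout:

    /lfp/data          (channels, samples) float32, microvolts
    /lfp/rate          scalar Hz
    /accel/data        (3, samples) + /accel/rate
    /temperature/time  seconds, /temperature/celsius
    /spikes/times      seconds
    /breath/data       displacement (pixels) + /breath/rate
    attrs: start_time, seed

Video travels separately (PNG frame directory); ground truth goes to CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import GroundTruth, Recording

__all__ = ["write_recording", "read_recording", "write_ground_truth",
           "read_ground_truth", "write_video_frames", "read_video_frames"]


def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        g.create_dataset("data", data=rec.lfp.astype(np.float32))
        g.create_dataset("rate", data=float(rec.lfp_rate_hz))
        if rec.accel is not None:
            g = f.create_group("accel")
            g.create_dataset("data", data=rec.accel.astype(np.float32))
            g.create_dataset("rate", data=float(rec.accel_rate_hz))
        if rec.temperature_c is not None:
            g = f.create_group("temperature")
            g.create_dataset("time", data=rec.temperature_time_s)
            g.create_dataset("celsius", data=rec.temperature_c)
        if rec.spike_times_s is not None:
            f.create_group("spikes").create_dataset("times", data=rec.spike_times_s)
        if rec.breath_displacement is not None:
            g = f.create_group("breath")
            g.create_dataset("data", data=rec.breath_displacement.astype(np.float32))
            g.create_dataset("rate", data=float(rec.breath_displacement_rate_hz))
        f.attrs["start_time"] = rec.start_time
        if rec.seed is not None:
            f.attrs["seed"] = rec.seed


def read_recording(path) -> Recording:
    """Read a Recording container, validating rates and shapes."""
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise KeyError("container missing required group '/lfp'")
        lfp = np.asarray(f["lfp/data"], float)
        rate = float(f["lfp/rate"][()])
        if rate <= 0:
            raise ValueError("corrupt container: LFP rate must be positive")
        if lfp.ndim != 2:
            raise ValueError("LFP data must be (channels, samples)")
        rec = Recording(lfp=lfp, lfp_rate_hz=rate)
        if "accel" in f:
            rec.accel = np.asarray(f["accel/data"], float)
            rec.accel_rate_hz = float(f["accel/rate"][()])
        if "temperature" in f:
            rec.temperature_time_s = np.asarray(f["temperature/time"], float)
            rec.temperature_c = np.asarray(f["temperature/celsius"], float)
        if "spikes" in f:
            rec.spike_times_s = np.asarray(f["spikes/times"], float)
        if "breath" in f:
            rec.breath_displacement = np.asarray(f["breath/data"], float)
            rec.breath_displacement_rate_hz = float(f["breath/rate"][()])
        rec.start_time = str(f.attrs.get("start_time", ""))
        seed = f.attrs.get("seed")
        rec.seed = int(seed) if seed is not None else None
    return rec


def write_ground_truth(prefix, truth: GroundTruth) -> None:
    """Ground truth as CSV tables under ``<prefix>_*.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.state_intervals,
                 columns=["start_s", "end_s", "label"]).to_csv(
        f"{prefix}_states.csv", index=False)
    for name, arr in [("shw", truth.shw_times_s),
                      ("twitch", truth.twitch_times_s),
                      ("eye", truth.eye_times_s),
                      ("spikes", truth.spike_times_s)]:
        pd.DataFrame({"time_s": arr}).to_csv(f"{prefix}_{name}.csv", index=False)
    pd.DataFrame({
        "cycle_start_s": truth.cycle_starts_s,
        "period_s": truth.cycle_periods_s,
    }).to_csv(f"{prefix}_cycles.csv", index=False)


def read_ground_truth(prefix) -> GroundTruth:
    prefix = Path(prefix)
    states = pd.read_csv(f"{prefix}_states.csv")
    cyc = pd.read_csv(f"{prefix}_cycles.csv")
    def col(name):
        return pd.read_csv(f"{prefix}_{name}.csv")["time_s"].to_numpy()
    periods = cyc["period_s"].to_numpy()
    return GroundTruth(
        state_intervals=[tuple(r) for r in states.itertuples(index=False)],
        cycle_starts_s=cyc["cycle_start_s"].to_numpy(),
        cycle_periods_s=periods,
        shw_times_s=col("shw"),
        twitch_times_s=col("twitch"),
        eye_times_s=col("eye"),
        spike_times_s=col("spikes"),
        breath_rate_hz=np.array([]),
        cycle_period_s=float(periods.mean()) if len(periods) else np.nan,
    )


def write_video_frames(directory, frames) -> None:
    import imageio.v3 as iio
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame)


def read_video_frames(directory) -> np.ndarray:
    import imageio.v3 as iio
    paths = sorted(Path(directory).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frames under {directory}")
    return np.stack([iio.imread(p) for p in paths])
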