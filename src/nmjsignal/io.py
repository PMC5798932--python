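"""File formats: multi-page TIFF movies, ROI/protocol JSON, sweep and trace CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import Movie, Roi
from .stim import StimulusTrain, build_train
from .ephys import SweepSet

__all__ = [
    "write_movie_tiff", "read_movie_tiff",
    "load_rois", "save_rois",
    "load_protocol", "save_protocol",
    "write_sweep_csv", "read_sweep_csv",
    "write_traces_csv",
]


def write_movie_tiff(movie: Movie, path: str | Path,
                     dtype: str = "uint16") -> None:
    """Write a movie as a multi-page TIFF (uint16 by default, or float32
    to preserve signed intermediates)."""
    if dtype == "uint16":
        data = np.clip(np.rint(movie.data), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = movie.data.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(str(path), data)


def read_movie_tiff(path: str | Path, frame_rate: float,
                    stim_onset: float = 0.0,
                    pixel_scale: float | None = None) -> Movie:
    """Read a multi-page TIFF as a :class:`Movie`.

    8-bit input is linearly rescaled to the 16-bit range (x 257, logged in
    provenance) so all downstream statistics are on the iu16 scale.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    log = [f"loaded {Path(path).name}"]
    if data.dtype == np.uint8:
        data = data.astype(np.float32) * 257.0
        log.append("rescaled 8-bit input to 16-bit range (x257)")
    return Movie(data=data.astype(np.float32), frame_rate=frame_rate,
                 stim_onset=stim_onset, pixel_scale=pixel_scale, log=log)


def save_rois(rois: list[Roi], path: str | Path) -> None:
    payload = [
        {"label": r.label, "kind": r.kind, "x": r.x, "y": r.y,
         "w": r.width, "h": r.height}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rois(path: str | Path) -> list[Roi]:
    payload = json.loads(Path(path).read_text())
    return [
        Roi(x=int(d["x"]), y=int(d["y"]), width=int(d["w"]),
            height=int(d["h"]), label=d.get("label", ""),
            kind=d.get("kind", "rectangle"))
        for d in payload
    ]


def save_protocol(train: StimulusTrain, path: str | Path) -> None:
    payload = {
        "frequency_hz": train.frequency,
        "onset_s": train.onset,
        "duration_s": train.duration,
        "pattern": train.pattern,
        "burst_on_s": train.burst_on,
        "duty_cycle": train.duty_cycle,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_protocol(path: str | Path) -> StimulusTrain:
    d = json.loads(Path(path).read_text())
    kwargs = {}
    if d.get("pattern", "tonic") == "phasic":
        kwargs = {"burst_on": d["burst_on_s"], "duty_cycle": d["duty_cycle"]}
    return build_train(
        frequency=d["frequency_hz"],
        onset=d.get("onset_s", 0.0),
        duration=d["duration_s"],
        pattern=d.get("pattern", "tonic"),
        **kwargs,
    )


def write_sweep_csv(sweep: SweepSet, path: str | Path) -> None:
    """Sweep as CSV (`time_s,vm_mv`) plus a JSON sidecar with stimulus
    times and sample rate."""
    df = pd.DataFrame({"time_s": sweep.time, "vm_mv": sweep.vm})
    df.to_csv(path, index=False)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({
        "sample_rate_hz": sweep.sample_rate,
        "stim_times_s": list(map(float, sweep.stim_times)),
        "cell_label": sweep.cell_label,
    }, indent=2))


def read_sweep_csv(path: str | Path) -> SweepSet:
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    t = df["time_s"].to_numpy()
    rate = meta.get("sample_rate_hz")
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    return SweepSet(
        time=t, vm=df["vm_mv"].to_numpy(), sample_rate=rate,
        stim_times=np.asarray(meta.get("stim_times_s", [])),
        cell_label=meta.get("cell_label", ""),
    )


def write_traces_csv(traces: list, path: str | Path) -> None:
    """Traces as long CSV (time_s, raw_iu16, dff_percent per ROI) plus a
    JSON sidecar with prestim statistics and peak dB."""
    from .statmaps import dff, to_decibels

    frames = []
    sidecar = {}
    for tr in traces:
        d = dff(tr) if tr.units == "iu16" and tr.prestim_mean > 0 else None
        frames.append(pd.DataFrame({
            "roi_label": tr.roi_label,
            "time_s": tr.time,
            "raw_iu16": tr.values if tr.units == "iu16" else tr.raw,
            "dff_percent": d.values if d is not None else np.nan,
        }))
        try:
            peak_db = to_decibels(tr)
        except ValueError:
            peak_db = float("nan")
        sidecar[tr.roi_label] = {
            "prestim_mean": tr.prestim_mean,
            "prestim_sd": tr.prestim_sd,
            "peak_db": peak_db,
        }
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
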