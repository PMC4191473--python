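"""File formats: TIFF stacks with YAML sidecars, epoch CSVs, map matrices.

Imaging sessions are written as one multi-page TIFF per sweep direction plus
a ``session.yaml`` sidecar carrying acquisition metadata and, for synthetic
sessions, the ground-truth block; the ROI mask travels as a 0/1 CSV matrix.
Epoch sets are CSV with time in the first column and one column per trial,
the header row carrying the condition labels.  Absolute maps are paired CSV
matrices (visual angle, amplitude) with a YAML sidecar and a PNG rendering
with a cyclic colormap and a degree-labelled colorbar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ephys import EpochSet
from .metrics import MapMetrics
from .retinotopy import AbsoluteRetinotopicMap
from .synth import ErgRecording, ImagingGroundTruth, ImagingSession

__all__ = [
    "write_imaging_session",
    "read_imaging_session",
    "write_epoch_set",
    "read_epoch_set",
    "write_erg_recording",
    "read_erg_recording",
    "write_absolute_map",
    "read_absolute_map",
    "write_map_metrics",
    "render_map_png",
]


def write_imaging_session(session: ImagingSession, outdir: str | Path) -> Path:
    """Write fwd/rev TIFF stacks, ROI mask CSV, and the YAML sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "stack_fwd.tif", session.stack_fwd.astype(np.float32))
    tifffile.imwrite(outdir / "stack_rev.tif", session.stack_rev.astype(np.float32))
    meta = {
        "frame_rate_hz": float(session.frame_rate_hz),
        "stim_freq_hz": float(session.stim_freq_hz),
        "direction_axis": session.axis,
        "pixel_size_mm": float(session.pixel_size_mm),
        "n_frames": int(session.n_frames),
    }
    gt = session.ground_truth
    if gt is not None:
        meta["ground_truth"] = gt.to_dict()
        if gt.roi_mask is not None:
            np.savetxt(outdir / "roi_mask.csv", gt.roi_mask.astype(int), fmt="%d", delimiter=",")
            meta["roi_mask_file"] = "roi_mask.csv"
    with open(outdir / "session.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return outdir


def read_imaging_session(indir: str | Path) -> ImagingSession:
    """Read a session written by :func:`write_imaging_session`."""
    indir = Path(indir)
    with open(indir / "session.yaml") as fh:
        meta = yaml.safe_load(fh)
    stacks = {}
    for name in ("stack_fwd", "stack_rev"):
        path = indir / f"{name}.tif"
        try:
            stacks[name] = tifffile.imread(path).astype(float)
        except Exception as exc:  # corrupt or unreadable file
            raise IOError(f"cannot read image stack {path}: {exc}") from exc
    gt = None
    if "ground_truth" in meta:
        roi = None
        if "roi_mask_file" in meta:
            roi = np.loadtxt(indir / meta["roi_mask_file"], delimiter=",").astype(bool)
        gt = ImagingGroundTruth.from_dict(meta["ground_truth"], roi_mask=roi)
    return ImagingSession(
        stack_fwd=stacks["stack_fwd"],
        stack_rev=stacks["stack_rev"],
        frame_rate_hz=meta["frame_rate_hz"],
        stim_freq_hz=meta["stim_freq_hz"],
        axis=meta["direction_axis"],
        pixel_size_mm=meta["pixel_size_mm"],
        ground_truth=gt,
    )


def write_epoch_set(epochs: EpochSet, path: str | Path) -> Path:
    """CSV: first column time (s), one column per trial, header = labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(epochs.trials.T, columns=list(epochs.labels))
    df.insert(0, "time", epochs.time)
    df.to_csv(path, index=False)
    return path


def read_epoch_set(path: str | Path) -> EpochSet:
    df = pd.read_csv(Path(path))
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    # pandas mangles duplicate headers to 'label.1', 'label.2', ...
    labels = [c.rsplit(".", 1)[0] if _is_dedup(c) else c for c in df.columns[1:]]
    return EpochSet(
        time=df["time"].to_numpy(),
        trials=df.iloc[:, 1:].to_numpy().T,
        labels=labels,
    )


def _is_dedup(col: str) -> bool:
    head, _, tail = col.rpartition(".")
    return bool(head) and tail.isdigit()


def write_erg_recording(erg: ErgRecording, path: str | Path) -> Path:
    """CSV with a '# flash_time_s=' comment line, then time,response."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# flash_time_s={erg.flash_time}\n")
        pd.DataFrame({"time": erg.time, "response": erg.trace}).to_csv(fh, index=False)
    return path


def read_erg_recording(path: str | Path) -> ErgRecording:
    path = Path(path)
    flash_time = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "flash_time_s=" in first:
            flash_time = float(first.split("flash_time_s=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return ErgRecording(
        time=df["time"].to_numpy(), trace=df["response"].to_numpy(), flash_time=flash_time
    )


def write_absolute_map(
    amap: AbsoluteRetinotopicMap, outdir: str | Path, png: bool = True
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "visual_angle.csv", amap.visual_angle, delimiter=",")
    np.savetxt(outdir / "amplitude.csv", amap.amplitude, delimiter=",")
    with open(outdir / "map.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "axis": amap.axis,
                "pixel_size_mm": float(amap.pixel_size_mm),
                "angle_conversion_factor": float(amap.angle_conversion_factor),
            },
            fh,
            sort_keys=False,
        )
    if png:
        render_map_png(amap, outdir / "map.png")
    return outdir


def read_absolute_map(indir: str | Path) -> AbsoluteRetinotopicMap:
    indir = Path(indir)
    with open(indir / "map.yaml") as fh:
        meta = yaml.safe_load(fh)
    return AbsoluteRetinotopicMap(
        visual_angle=np.loadtxt(indir / "visual_angle.csv", delimiter=","),
        amplitude=np.loadtxt(indir / "amplitude.csv", delimiter=","),
        axis=meta["axis"],
        pixel_size_mm=meta["pixel_size_mm"],
        angle_conversion_factor=meta["angle_conversion_factor"],
    )


def render_map_png(amap: AbsoluteRetinotopicMap, path: str | Path) -> Path:
    """Render the visual-angle map with a cyclic colormap and degree colorbar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(amap.visual_angle, cmap="hsv")
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("visual angle (deg)")
    ax.set_title(f"{amap.axis} map")
    ax.set_xlabel("mediolateral (px)")
    ax.set_ylabel("anteroposterior (px)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_map_metrics(
    metrics: MapMetrics, json_path: str | Path, table_path: str | Path | None = None,
    session_id: str = "session",
) -> None:
    """Write one metrics record (JSON) and append to the experiment table (CSV)."""
    json_path = Path(json_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
        fh.write("\n")
    if table_path is not None:
        table_path = Path(table_path)
        row = pd.DataFrame([{"session_id": session_id, **metrics.to_dict()}])
        header = not table_path.exists()
        row.to_csv(table_path, mode="a", header=header, index=False)
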