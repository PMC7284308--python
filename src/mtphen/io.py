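"""File round trips: TIFF stacks/movies with JSON calibration sidecars,
CSV tables for ground truth, per-object results and traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .contraction import ContractionProfile
from .reconstruction import Nucleus3D
from .stack import ImageStack
from .traces import APTrace, CalciumTrace

__all__ = [
    "write_stack",
    "read_stack",
    "write_movie",
    "read_movie",
    "write_trace_csv",
    "read_trace_csv",
    "nuclei_to_frame",
    "write_profile_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Multi-page TIFF in (channel, z) page order plus a JSON sidecar with
    the calibration and channel names."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata=None)
    meta = {
        "um_per_px": stack.um_per_px,
        "z_step_um": stack.z_step_um,
        "channel_names": list(stack.channel_names),
        "shape": list(stack.data.shape),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path).reshape(meta["shape"])
    return ImageStack(
        data,
        um_per_px=meta["um_per_px"],
        z_step_um=meta["z_step_um"],
        channel_names=tuple(meta["channel_names"]),
    )


def write_movie(
    frames: np.ndarray, path: str | Path, fps: float, um_per_px: float
) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames))
    _sidecar(path).write_text(
        json.dumps({"fps": fps, "um_per_px": um_per_px})
    )


def read_movie(path: str | Path) -> tuple[np.ndarray, float, float]:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return tifffile.imread(path), meta["fps"], meta["um_per_px"]


def write_trace_csv(
    trace: APTrace | CalciumTrace, path: str | Path
) -> None:
    """Two-column CSV (time, value)."""
    if isinstance(trace, APTrace):
        df = pd.DataFrame({"time_ms": trace.time_ms, "v_mv": trace.v_mv})
    else:
        df = pd.DataFrame({"time_s": trace.time_s, "dff": trace.dff})
    df.to_csv(path, index=False)


def read_trace_csv(
    path: str | Path, kind: str = "ap", rate: float | None = None
) -> APTrace | CalciumTrace:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    if kind == "ap":
        return APTrace(time_ms=t, v_mv=v, rate_khz=rate)
    return CalciumTrace(time_s=t, dff=v, rate_hz=rate)


def nuclei_to_frame(nuclei: list[Nucleus3D]) -> pd.DataFrame:
    """Flatten reconstructed nuclei to one row per object."""
    rows = []
    for i, n in enumerate(nuclei):
        a, b, c = n.semi_axes_um
        cz, cy, cx = n.centroid_um
        rows.append(
            dict(
                id=i,
                z_first=n.slice_range[0],
                z_last=n.slice_range[1],
                n_sections=n.n_sections,
                centroid_z_um=cz,
                centroid_y_um=cy,
                centroid_x_um=cx,
                a_um=a,
                b_um=b,
                c_um=c,
                volume_um3=n.volume_um3,
                orientation=n.orientation,
                identity=n.identity,
                proliferative=n.proliferative,
            )
        )
    return pd.DataFrame(rows)


def write_profile_csv(profile: ContractionProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": profile.time_s,
            "speed_um_s": profile.speed_um_s,
            "sd_um_s": profile.sd_um_s,
        }
    ).to_csv(path, index=False)
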