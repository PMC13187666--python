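"""File-format adapters: AE/psi/anatomy CSV dialects and image-stack directories.

CSV dialect everywhere: comma separated, dot decimal, mandatory header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ae import AEEventLog
from .anatomy import AnatomySample, ConduitMeasure, WallPair
from .exceptions import ConfigError
from .ov import ImageStack
from .psi import PsiMeasurement

AE_COLUMNS = ["time_s", "amplitude_db", "plant_id"]
PSI_COLUMNS = ["time_s", "psi_mpa", "plant_id"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")


def read_ae_csv(path, detection_threshold: float = 35.0) -> dict[str, AEEventLog]:
    """AE hit log(s), one AEEventLog per plant_id."""
    df = pd.read_csv(path)
    _require_columns(df, AE_COLUMNS, path)
    out = {}
    for plant_id, sub in df.groupby("plant_id", sort=True):
        sub = sub.sort_values("time_s", kind="stable")
        out[str(plant_id)] = AEEventLog(
            times=sub["time_s"].to_numpy(dtype=float),
            amplitudes=sub["amplitude_db"].to_numpy(dtype=float),
            plant_id=str(plant_id), detection_threshold=detection_threshold)
    return out


def read_psi_csv(path) -> list[PsiMeasurement]:
    df = pd.read_csv(path)
    _require_columns(df, PSI_COLUMNS, path)
    return [PsiMeasurement(time=float(r.time_s), psi=float(r.psi_mpa),
                           plant_id=str(r.plant_id))
            for r in df.itertuples(index=False)]


def read_image_stack(directory, manifest: str = "manifest.csv",
                     pixel_scale: float | None = None) -> ImageStack:
    """Frame directory with a manifest (`frame,filename,time_s`); frames are
    single-channel TIFF or PNG."""
    import imageio.v3 as iio

    directory = Path(directory)
    mpath = directory / manifest
    if not mpath.exists():
        raise ConfigError(f"manifest not found: {mpath}")
    man = pd.read_csv(mpath)
    _require_columns(man, ["frame", "filename", "time_s"], mpath)
    man = man.sort_values("frame", kind="stable")
    frames = []
    for fname in man["filename"]:
        img = np.asarray(iio.imread(directory / fname))
        if img.ndim == 3:  # collapse accidental RGB to grayscale
            img = img.mean(axis=-1)
        frames.append(img.astype(np.float32))
    return ImageStack(frames=np.stack(frames),
                      times=man["time_s"].to_numpy(dtype=float),
                      pixel_scale=pixel_scale)


def read_conduit_csv(path) -> dict[str, list[ConduitMeasure]]:
    """`sample_id,lumen_area_um2,shape` -> conduits grouped by sample."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "lumen_area_um2", "shape"], path)
    out: dict[str, list[ConduitMeasure]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.sample_id), []).append(
            ConduitMeasure(lumen_area=float(r.lumen_area_um2),
                           shape_model=str(r.shape)))
    return out


def read_wallpair_csv(path) -> dict[str, list[WallPair]]:
    """`sample_id,t_um,span_um` -> wall pairs grouped by sample."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "t_um", "span_um"], path)
    out: dict[str, list[WallPair]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.sample_id), []).append(
            WallPair(t=float(r.t_um), span=float(r.span_um)))
    return out


def assemble_samples(conduits: dict[str, list[ConduitMeasure]],
                     wall_pairs: dict[str, list[WallPair]] | None = None,
                     ) -> list[AnatomySample]:
    wall_pairs = wall_pairs or {}
    return [AnatomySample(conduits=cs, wall_pairs=wall_pairs.get(sid, []),
                          sample_id=sid)
            for sid, cs in sorted(conduits.items())]


def write_timeline_csv(timeline, path) -> None:
    timeline.to_frame().to_csv(path, index=False)


def write_ov_series_csv(series, path) -> None:
    series.to_frame().to_csv(path, index=False)
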