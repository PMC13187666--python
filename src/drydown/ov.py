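"""Optical embolism detection by successive-frame differencing.

Successive frames of a drydown stack are subtracted; above-threshold pixel
clusters are embolism events.  A running union mask prevents a pixel from
being counted twice.  Cumulative embolized area is converted to percent of
the final embolized area and coupled to the psi timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import measure

from .exceptions import AnalysisError, ConfigError
from .psi import PsiTimeline, psi_at

__all__ = [
    "ImageStack",
    "EmbolismEventMap",
    "OVSeries",
    "difference_stack",
    "detect_events",
    "accumulate_area",
    "robust_noise_sd",
]

_CONNECTIVITY = {4: 1, 8: 2}  # pixel connectivity -> skimage connectivity rank


@dataclass
class ImageStack:
    """Ordered grayscale frames with acquisition times (nominal 150 s apart)."""

    frames: np.ndarray          # (n_frames, h, w)
    times: np.ndarray           # s, strictly increasing
    pixel_scale: float | None = None  # um per pixel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigError("frames must be a (n, h, w) array of grayscale images")
        if len(self.frames) < 2:
            raise ConfigError("need at least 2 frames")
        if len(self.times) != len(self.frames):
            raise ConfigError("one timestamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class EmbolismEventMap:
    """Detected events per frame pair plus the running union mask.

    ``events`` has one row per accepted cluster: pair_index, area_px,
    centroid_row, centroid_col, time_mid_s.  ``union_mask`` holds every
    pixel ever flagged as embolized (non-shrinking by construction).
    """

    events: pd.DataFrame
    union_mask: np.ndarray
    threshold: float
    min_cluster: int
    connectivity: int
    n_pairs: int

    def area_per_pair(self) -> np.ndarray:
        """Newly embolized pixel area per frame pair (0 where no events)."""
        out = np.zeros(self.n_pairs)
        if len(self.events):
            grouped = self.events.groupby("pair_index")["area_px"].sum()
            out[grouped.index.to_numpy()] = grouped.to_numpy()
        return out


@dataclass
class OVSeries:
    """Cumulative embolized area versus time / psi (one row per frame pair)."""

    time: np.ndarray       # midpoint of each frame pair, s
    a_cum: np.ndarray      # cumulative embolized area, px
    percent: np.ndarray    # 100 * a_cum / a_max
    a_max: float           # final cumulative area, px
    psi: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.time, "a_cum_px": self.a_cum, "percent": self.percent}
        if self.psi is not None:
            d["psi_mpa"] = self.psi
        return pd.DataFrame(d)


def difference_stack(stack: ImageStack) -> np.ndarray:
    """Absolute successive-frame differences: |frame[i+1] - frame[i]|."""
    frames = stack.frames.astype(float)
    return np.abs(np.diff(frames, axis=0))


def robust_noise_sd(diff_map: np.ndarray) -> float:
    """Robust noise scale of a difference map (scaled median absolute deviation)."""
    return float(sps.median_abs_deviation(diff_map, axis=None, scale="normal"))


def detect_events(diff_maps: np.ndarray, threshold: float | None = None,
                  min_cluster: int = 4, connectivity: int = 8,
                  roi_mask: np.ndarray | None = None) -> EmbolismEventMap:
    """Group above-threshold difference pixels into embolism events.

    Parameters
    ----------
    diff_maps : (n_pairs, h, w) array
        Output of :func:`difference_stack`.
    threshold : float, optional
        Intensity cutoff; default is 3x the robust noise sd of the first
        difference map (floored at a tiny epsilon for noise-free input).
    min_cluster : int
        Minimum connected-component area in px; smaller clusters are
        discarded (sub-resolution events are invisible).
    connectivity : {4, 8}
        Pixel connectivity for component labeling.
    roi_mask : bool array, optional
        Restrict detection to a region of interest (default: full frame).

    Pixels already in the union mask are excluded before labeling, so an
    area is never double-counted across frame pairs.
    """
    diff_maps = np.asarray(diff_maps, dtype=float)
    if diff_maps.ndim != 3:
        raise ConfigError("diff_maps must be (n_pairs, h, w)")
    if connectivity not in _CONNECTIVITY:
        raise ConfigError("connectivity must be 4 or 8")
    if threshold is None:
        threshold = max(3.0 * robust_noise_sd(diff_maps[0]), 1e-9)
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    if min_cluster < 1:
        raise ConfigError("min_cluster must be >= 1")

    union = np.zeros(diff_maps.shape[1:], dtype=bool)
    rows = []
    for k, dmap in enumerate(diff_maps):
        mask = dmap > threshold
        if roi_mask is not None:
            mask &= roi_mask
        mask &= ~union
        if not mask.any():
            continue
        labels = measure.label(mask, connectivity=_CONNECTIVITY[connectivity])
        for region in measure.regionprops(labels):
            if region.area < min_cluster:
                continue
            rows.append({"pair_index": k, "area_px": int(region.area),
                         "centroid_row": region.centroid[0],
                         "centroid_col": region.centroid[1]})
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            union[rr, cc] = True
    events = pd.DataFrame(rows, columns=["pair_index", "area_px",
                                         "centroid_row", "centroid_col"])
    return EmbolismEventMap(events=events, union_mask=union,
                            threshold=float(threshold), min_cluster=min_cluster,
                            connectivity=connectivity, n_pairs=len(diff_maps))


def accumulate_area(events: EmbolismEventMap, stack: ImageStack,
                    timeline: PsiTimeline | None = None,
                    extrapolation: str = "clamp") -> OVSeries:
    """Cumulative embolized area and percent-of-final series.

    percent = 100 * a_cum / a_max, where a_max is the cumulative area at the
    end of the record.  Each frame pair is assigned the midpoint of its two
    acquisition times; psi (if a timeline is given) is evaluated there.
    """
    if len(events.events) == 0:
        raise AnalysisError("no embolism events detected")
    added = events.area_per_pair()
    a_cum = np.cumsum(added)
    a_max = float(a_cum[-1])
    if a_max <= 0:
        raise AnalysisError("degenerate series: zero total embolized area")
    percent = 100.0 * a_cum / a_max
    t_mid = 0.5 * (stack.times[:-1] + stack.times[1:])
    psi = None
    if timeline is not None:
        psi = np.asarray(psi_at(timeline, t_mid, extrapolation), dtype=float)
    return OVSeries(time=t_mid, a_cum=a_cum, percent=percent, a_max=a_max, psi=psi)
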