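"""Water-potential timelines from discrete pressure-chamber readings.

Readings taken on 2-3 plants at (roughly) the same moment are averaged into
a single knot; psi at an arbitrary time is obtained by exact linear
interpolation between consecutive knots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, TimelineError

__all__ = ["PsiMeasurement", "PsiTimeline", "build_timeline", "psi_at"]


@dataclass(frozen=True)
class PsiMeasurement:
    """One pressure-chamber reading: time (s from drydown start), psi (MPa <= 0)."""

    time: float
    psi: float
    plant_id: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ConfigError(f"measurement time must be >= 0, got {self.time}")
        if self.psi > 0:
            raise ConfigError(f"psi must be <= 0 MPa, got {self.psi}")


@dataclass
class PsiTimeline:
    """Piecewise-linear psi(t) through per-timepoint-averaged knots.

    Knot times are strictly increasing.  Knot psi values are kept exactly as
    measured; a non-monotone sequence (psi increasing with time) is allowed
    but flagged via ``monotone`` and a warning at construction.
    """

    times: np.ndarray
    psis: np.ndarray
    monotone: bool = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.psis = np.asarray(self.psis, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.psis.shape:
            raise TimelineError("times and psis must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise TimelineError(f"need >= 2 knots, got {len(self.times)}")
        if np.any(np.diff(self.times) <= 0):
            raise TimelineError("knot times must be strictly increasing")
        self.monotone = bool(np.all(np.diff(self.psis) <= 0))
        if not self.monotone:
            warnings.warn("psi knots are not monotonically non-increasing "
                          "(measurement noise?); kept as measured", stacklevel=2)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def __call__(self, t, extrapolation: str = "clamp"):
        return psi_at(self, t, extrapolation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "psi_mpa": self.psis})


def _group_indices(times: np.ndarray, tolerance: float) -> list[np.ndarray]:
    """Cluster sorted reading times: a new group starts whenever the gap to
    the previous reading exceeds ``tolerance`` (single-linkage on the line)."""
    order = np.argsort(times, kind="stable")
    groups, current = [], [order[0]]
    for i in order[1:]:
        if times[i] - times[current[-1]] > tolerance:
            groups.append(np.asarray(current))
            current = [i]
        else:
            current.append(i)
    groups.append(np.asarray(current))
    return groups


def build_timeline(measurements, grouping_tolerance: float = 0.0) -> PsiTimeline:
    """Average readings taken within ``grouping_tolerance`` seconds of each
    other into single knots and return the resulting timeline.

    ``measurements`` may be a list of :class:`PsiMeasurement` or a DataFrame
    with ``time_s`` and ``psi_mpa`` columns.

    Raises
    ------
    TimelineError
        If fewer than two knots remain after grouping.
    """
    if isinstance(measurements, pd.DataFrame):
        times = measurements["time_s"].to_numpy(dtype=float)
        psis = measurements["psi_mpa"].to_numpy(dtype=float)
    else:
        measurements = list(measurements)
        times = np.array([m.time for m in measurements], dtype=float)
        psis = np.array([m.psi for m in measurements], dtype=float)
    if len(times) == 0:
        raise TimelineError("no measurements supplied")
    if grouping_tolerance < 0:
        raise ConfigError("grouping_tolerance must be >= 0")
    groups = _group_indices(times, grouping_tolerance)
    knot_t = np.array([times[g].mean() for g in groups])
    knot_psi = np.array([psis[g].mean() for g in groups])
    if len(knot_t) < 2:
        raise TimelineError(
            f"only {len(knot_t)} timepoint(s) after grouping; need >= 2 to interpolate")
    return PsiTimeline(times=knot_t, psis=knot_psi)


def psi_at(timeline: PsiTimeline, t, extrapolation: str = "clamp"):
    """Evaluate psi(t) by linear interpolation between bracketing knots.

    ``extrapolation`` controls behaviour outside [t_first, t_last]:
    ``"clamp"`` holds the end values (with a warning), ``"linear"`` extends
    the end segments, ``"error"`` raises :class:`TimelineError`.
    """
    if extrapolation not in ("clamp", "linear", "error"):
        raise ConfigError(f"unknown extrapolation policy {extrapolation!r}")
    t_arr = np.asarray(t, dtype=float)
    t0, t1 = timeline.range
    outside = (t_arr < t0) | (t_arr > t1)
    if np.any(outside):
        if extrapolation == "error":
            raise TimelineError(f"time(s) outside measured range [{t0}, {t1}]")
        if extrapolation == "clamp":
            warnings.warn("evaluating psi outside the measured range; "
                          "clamping to end values", stacklevel=2)
    out = np.interp(t_arr, timeline.times, timeline.psis)
    if extrapolation == "linear" and np.any(outside):
        lo = t_arr < t0
        hi = t_arr > t1
        s0 = (timeline.psis[1] - timeline.psis[0]) / (timeline.times[1] - timeline.times[0])
        s1 = (timeline.psis[-1] - timeline.psis[-2]) / (timeline.times[-1] - timeline.times[-2])
        out = np.where(lo, timeline.psis[0] + s0 * (t_arr - t0), out)
        out = np.where(hi, timeline.psis[-1] + s1 * (t_arr - t1), out)
    return float(out) if np.ndim(t) == 0 else out
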