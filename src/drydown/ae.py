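"""Acoustic-emission activity analysis.

Hit logs are binned into 1-min activity (signals per minute), smoothed with
a Savitzky-Golay filter, coupled to the water-potential timeline, and the
psi at the main activity peak (the 50 %-embolism proxy) is extracted per
individual, then summarized per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .exceptions import AnalysisError, ConfigError
from .psi import PsiTimeline, psi_at

__all__ = [
    "AEEventLog",
    "ActivitySeries",
    "AEResult",
    "bin_activity",
    "smooth_activity",
    "attach_psi",
    "find_psi_aemax",
    "peak_diagnostics",
    "summarize_group",
]


@dataclass
class AEEventLog:
    """Time-sorted acoustic hits for one plant."""

    times: np.ndarray       # s from drydown start, non-decreasing
    amplitudes: np.ndarray  # dB, all >= detection_threshold
    plant_id: str = ""
    detection_threshold: float = 35.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ConfigError("times and amplitudes must have equal length")
        if np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.amplitudes = self.amplitudes[order]
        if len(self.amplitudes) and np.any(self.amplitudes < self.detection_threshold):
            raise ConfigError(
                f"amplitudes below the {self.detection_threshold} dB detection threshold")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ActivitySeries:
    """Per-bin acoustic activity; bins are contiguous half-open [start, start+width)."""

    bin_start: np.ndarray
    rate: np.ndarray                    # signals per bin = signals min^-1 at 60 s bins
    bin_width: float = 60.0
    smoothed_rate: np.ndarray | None = None
    psi: np.ndarray | None = None
    plant_id: str = ""
    smoothing: dict = field(default_factory=dict)

    @property
    def bin_mid(self) -> np.ndarray:
        return self.bin_start + 0.5 * self.bin_width


@dataclass(frozen=True)
class AEResult:
    """Group summary of per-individual psi-at-peak values (mean +/- SE)."""

    group_mean: float
    group_se: float
    n: int
    values: tuple[float, ...] = ()


def bin_activity(log: AEEventLog, bin_width: float = 60.0) -> ActivitySeries:
    """Count hits in contiguous half-open bins starting at t = 0.

    With the default 60 s width the count per bin is the activity in
    signals per minute.  Empty bins are present with rate 0; the total over
    bins always equals the number of hits.
    """
    if len(log) == 0:
        raise AnalysisError("empty AE log: no activity to bin")
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    idx = np.floor(log.times / bin_width).astype(int)
    if np.any(idx < 0):
        raise ConfigError("negative hit times")
    counts = np.bincount(idx)
    starts = np.arange(len(counts)) * bin_width
    return ActivitySeries(bin_start=starts, rate=counts.astype(float),
                          bin_width=bin_width, plant_id=log.plant_id)


def smooth_activity(series: ActivitySeries, window: int = 31,
                    polyorder: int = 3) -> ActivitySeries:
    """Savitzky-Golay smooth of the activity; negative output floored at 0.

    ``window`` must be odd, larger than ``polyorder`` and no longer than the
    series.  Returns a new series with ``smoothed_rate`` set and the
    parameters echoed in ``smoothing``.
    """
    n = len(series.rate)
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ConfigError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > n:
        raise ConfigError(f"window ({window}) longer than series ({n})")
    smoothed = signal.savgol_filter(series.rate, window, polyorder)
    smoothed = np.clip(smoothed, 0.0, None)
    return replace(series, smoothed_rate=smoothed,
                   smoothing={"window": window, "polyorder": polyorder})


def attach_psi(series: ActivitySeries, timeline: PsiTimeline,
               extrapolation: str = "clamp") -> ActivitySeries:
    """Attach psi evaluated at each bin midpoint (events are only localized
    to a bin, so the midpoint is within 30 s of any hit in it)."""
    psi = psi_at(timeline, series.bin_mid, extrapolation)
    return replace(series, psi=np.asarray(psi, dtype=float))


def find_psi_aemax(series: ActivitySeries) -> float:
    """Psi at the global maximum of the smoothed activity (the main peak).

    Ties (including plateaus) are broken toward the most negative psi.
    """
    if series.smoothed_rate is None:
        raise AnalysisError("smoothed_rate not computed; call smooth_activity first")
    if series.psi is None:
        raise AnalysisError("psi not attached; call attach_psi first")
    s = series.smoothed_rate
    if np.all(s <= 0):
        raise AnalysisError("activity is all zero: no peak")
    peak = s.max()
    at_peak = np.flatnonzero(s == peak)
    return float(series.psi[at_peak].min())


def peak_diagnostics(series: ActivitySeries, prominence: float | None = None):
    """Secondary-peak diagnostics: local maxima of the smoothed activity.

    Returns a list of ``(psi, smoothed_rate)`` tuples sorted by decreasing
    rate; the first entry is the main peak.
    """
    if series.smoothed_rate is None or series.psi is None:
        raise AnalysisError("requires smoothed_rate and psi")
    idx, _ = signal.find_peaks(series.smoothed_rate, prominence=prominence)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(series.smoothed_rate))])
    order = np.argsort(series.smoothed_rate[idx])[::-1]
    return [(float(series.psi[i]), float(series.smoothed_rate[i])) for i in idx[order]]


def summarize_group(values) -> AEResult:
    """Mean +/- standard error of per-individual values (SE = sd/sqrt(n);
    0 for a single individual)."""
    values = np.asarray(list(values), dtype=float)
    n = len(values)
    if n == 0:
        raise AnalysisError("no values to summarize")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return AEResult(group_mean=mean, group_se=se, n=n, values=tuple(values))
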