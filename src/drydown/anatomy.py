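"""Conduit and xylem anatomy metrics.

Diameters come from lumen areas under a shape model (squares for conifer
tracheids, circles for angiosperm vessels); species means are hierarchical
(per sample first, then across samples).  The hydraulic diameter is the
conductivity-weighted mean sum(d^5)/sum(d^4), and wall reinforcement
(t/span)^2 is averaged over conduit pairs whose span lies within 1 um of
the hydraulic diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AnalysisError, ConfigError

__all__ = [
    "ConduitMeasure",
    "WallPair",
    "AnatomySample",
    "AnatomySummary",
    "diameter_from_area",
    "hierarchical_mean",
    "hydraulic_diameter",
    "select_pairs",
    "wall_reinforcement",
    "class_histogram",
    "xylem_geometry",
    "summarize_sample",
]


@dataclass(frozen=True)
class ConduitMeasure:
    """One conduit lumen: area (um^2) and its derived diameter under a shape model."""

    lumen_area: float
    shape_model: str = "circle"  # "circle" | "square"

    @property
    def diameter(self) -> float:
        return diameter_from_area(self.lumen_area, self.shape_model)


@dataclass(frozen=True)
class WallPair:
    """Double wall thickness t and conduit span (the diameter entering (t/b)^2)."""

    t: float
    span: float

    def __post_init__(self) -> None:
        if self.t <= 0 or self.span <= 0:
            raise ConfigError("wall thickness and span must be > 0")
        if self.t >= 2.0 * self.span:
            raise ConfigError(f"implausible wall pair: t={self.t} vs span={self.span}")


@dataclass
class AnatomySample:
    """Measurements from one hypocotyl cross-section."""

    conduits: list[ConduitMeasure]
    wall_pairs: list[WallPair] = field(default_factory=list)
    xylem_width_points: tuple[float, ...] | None = None  # 4 cardinal readings, um
    xylem_area: float | None = None        # um^2
    section_area: float | None = None      # um^2
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.conduits) < 1:
            raise ConfigError("a sample needs at least one conduit")
        if self.xylem_width_points is not None and len(self.xylem_width_points) != 4:
            raise ConfigError("xylem width requires exactly 4 cardinal readings")

    @property
    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.conduits])


@dataclass
class AnatomySummary:
    """Per-sample (or per-species) anatomy metrics."""

    d_mean: float
    d_h: float
    twb2: float | None
    n_conduits: int
    class_hist: np.ndarray
    xylem_width: float | None = None
    xylem_area_prop: float | None = None


def diameter_from_area(area, shape_model: str = "circle"):
    """Equivalent diameter of a lumen area: 2*sqrt(area/pi) for circles,
    sqrt(area) for squares."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ConfigError("lumen area must be > 0")
    if shape_model == "circle":
        d = 2.0 * np.sqrt(area / np.pi)
    elif shape_model == "square":
        d = np.sqrt(area)
    else:
        raise ConfigError(f"unknown shape model {shape_model!r}")
    return float(d) if np.ndim(d) == 0 else d


def hierarchical_mean(per_sample_values) -> tuple[float, float]:
    """Mean of per-sample means (NOT the pooled mean) and the SE across samples.

    This weights every sample equally regardless of how many conduits were
    measured in it.  A single sample yields SE 0 with a warning.
    """
    sample_means = []
    for vals in per_sample_values:
        vals = np.asarray(list(vals), dtype=float)
        if len(vals) == 0:
            raise AnalysisError("empty sample in hierarchical mean")
        sample_means.append(vals.mean())
    sample_means = np.asarray(sample_means)
    if len(sample_means) == 0:
        raise AnalysisError("no samples")
    if len(sample_means) == 1:
        warnings.warn("single sample: SE undefined, reported as 0", stacklevel=2)
        return float(sample_means[0]), 0.0
    se = float(sample_means.std(ddof=1) / np.sqrt(len(sample_means)))
    return float(sample_means.mean()), se


def hydraulic_diameter(diameters) -> float:
    """Hydraulically weighted mean diameter sum(d^5) / sum(d^4)."""
    d = np.asarray(list(diameters), dtype=float)
    if len(d) == 0:
        raise AnalysisError("no diameters")
    if np.any(d <= 0):
        raise ConfigError("diameters must be > 0")
    d4 = d ** 4
    return float(np.sum(d4 * d) / np.sum(d4))


def select_pairs(pairs, d_h: float, tolerance: float = 1.0) -> list[WallPair]:
    """Wall pairs whose span lies within ``d_h +/- tolerance`` um."""
    return [p for p in pairs if d_h - tolerance <= p.span <= d_h + tolerance]


def wall_reinforcement(pairs, d_h: float, tolerance: float = 1.0,
                       min_pairs: int = 20) -> float:
    """Mean (t/span)^2 over pairs with span within ``d_h +/- tolerance``.

    Warns when fewer than ``min_pairs`` qualify; raises
    :class:`AnalysisError` when none do.
    """
    selected = select_pairs(pairs, d_h, tolerance)
    if not selected:
        raise AnalysisError(
            f"no wall pairs with span within {d_h} +/- {tolerance} um")
    if len(selected) < min_pairs:
        warnings.warn(f"only {len(selected)} wall pairs qualify "
                      f"(< {min_pairs} recommended)", stacklevel=2)
    ratios = np.array([(p.t / p.span) ** 2 for p in selected])
    return float(ratios.mean())


def class_histogram(diameters, width: float = 1.0) -> np.ndarray:
    """Counts per half-open diameter class [k*width, (k+1)*width).

    The returned array is indexed by class number k; counts sum to the
    number of conduits.
    """
    d = np.asarray(list(diameters), dtype=float)
    if width <= 0:
        raise ConfigError("class width must be > 0")
    if len(d) == 0:
        return np.zeros(0, dtype=int)
    if np.any(d <= 0):
        raise ConfigError("diameters must be > 0")
    return np.bincount(np.floor(d / width).astype(int))


def xylem_geometry(sample: AnatomySample) -> tuple[float | None, float | None]:
    """(mean cardinal xylem width, xylem area as % of section area).

    Either entry is None when the underlying measurements are absent.
    """
    width = None
    if sample.xylem_width_points is not None:
        width = float(np.mean(sample.xylem_width_points))
    prop = None
    if sample.xylem_area is not None and sample.section_area is not None:
        if sample.section_area <= 0 or sample.xylem_area <= 0:
            raise ConfigError("areas must be > 0")
        prop = 100.0 * sample.xylem_area / sample.section_area
    return width, prop


def summarize_sample(sample: AnatomySample, wall_tolerance: float = 1.0,
                     min_pairs: int = 20, class_width: float = 1.0) -> AnatomySummary:
    """All per-sample metrics in one pass (Table-style row for one section)."""
    d = sample.diameters
    d_h = hydraulic_diameter(d)
    twb2 = None
    if sample.wall_pairs:
        try:
            twb2 = wall_reinforcement(sample.wall_pairs, d_h, wall_tolerance, min_pairs)
        except AnalysisError:
            twb2 = None
    width, prop = xylem_geometry(sample)
    return AnatomySummary(d_mean=float(d.mean()), d_h=d_h, twb2=twb2,
                          n_conduits=len(d),
                          class_hist=class_histogram(d, class_width),
                          xylem_width=width, xylem_area_prop=prop)
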