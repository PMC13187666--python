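"""Synthetic drydown experiments with known ground truth.

Generates a conduit population (diameter mixture + per-conduit embolism
thresholds drawn from a Weibull tension distribution), a monotone psi(t)
trajectory, an acoustic hit stream (one hit per embolizing conduit plus an
optional late-drydown nuisance process that keeps emissions from
plateauing), an optical image stack (conduits rendered as disks whose
intensity steps at embolism; sub-resolution conduits invisible), and noisy
pressure-chamber psi readings on 2-3 plants per timepoint.

Every random draw comes from a named substream of one master seed, so a
dataset is byte-reproducible and the generating parameters travel with it
for parameter-recovery scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import draw

from .ae import AEEventLog
from .exceptions import ConfigError, GenerationError
from .ov import ImageStack
from .psi import PsiMeasurement, PsiTimeline

__all__ = [
    "SyntheticConfig",
    "DrydownTruth",
    "ConduitPopulation",
    "SyntheticDataset",
    "gen_conduit_population",
    "gen_psi_trajectory",
    "gen_ae_stream",
    "gen_ov_stack",
    "gen_psi_measurements",
    "first_crossing_times",
    "visible_mask",
    "simulate",
    "write_dataset",
]

_STREAMS = ("population", "thresholds", "positions", "nuisance",
            "amplitudes", "noise", "sampling")

MAX_DURATION_S = 72_000.0  # 20 h bench drydown


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent RNG substreams spawned from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic experiment (defaults are placeholders, not
    calibrated to any real acquisition)."""

    # conduit population
    n_conduits: int = 400
    region_um: tuple[float, float] = (200.0, 200.0)
    body_median_um: float = 8.0          # lognormal body of the diameter mixture
    body_sigma: float = 0.45
    small_class_fraction: float = 0.0    # point mass emulating a 1-um class
    small_class_range: tuple[float, float] = (0.5, 1.5)
    small_threshold_shift_mpa: float = 0.0  # <0: small conduits more resistant
    min_separation_um: float = 0.0       # dart-throwing spacing (0 = off)
    # acoustic stream
    nuisance_rate0_hz: float = 0.0       # nuisance Poisson base rate at onset
    nuisance_growth_per_s: float = 2e-4  # exponential growth of nuisance rate
    nuisance_onset_frac: float = 0.6     # onset as a fraction of the duration
    amplitude_mean_db: float = 45.0
    amplitude_sd_db: float = 6.0
    detection_threshold_db: float = 35.0
    # optical stack
    frame_interval_s: float = 150.0
    pixel_scale_um: float = 1.0
    noise_sd: float = 0.0
    embolism_delta: float = 40.0
    background: float = 100.0
    lumen_offset: float = -10.0
    min_detectable_px: float = 1.0
    # pressure-chamber sampling
    psi_sample_interval_s: float = 3600.0
    psi_noise_sd_mpa: float = 0.0
    plants_per_timepoint: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        if self.n_conduits <= 0:
            raise ConfigError(f"n_conduits must be > 0, got {self.n_conduits}")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        if self.pixel_scale_um <= 0:
            raise ConfigError("pixel_scale_um must be > 0")
        if not 0 <= self.small_class_fraction < 1:
            raise ConfigError("small_class_fraction must be in [0, 1)")
        if self.body_median_um <= 0 or self.body_sigma <= 0:
            raise ConfigError("diameter mixture parameters must be > 0")
        if self.small_threshold_shift_mpa > 0:
            raise ConfigError("small_threshold_shift_mpa must be <= 0 "
                              "(shift toward more negative thresholds)")
        if any(k < 1 for k in self.plants_per_timepoint):
            raise ConfigError("plants_per_timepoint entries must be >= 1")


@dataclass
class DrydownTruth:
    """Generating parameters of one drydown: psi(t) knots and the Weibull
    threshold distribution (tension scale MPa, dimensionless shape)."""

    psi_knots_t: np.ndarray
    psi_knots_mpa: np.ndarray
    weibull_scale: float
    weibull_shape: float
    seed: int
    duration_s: float

    def __post_init__(self) -> None:
        self.psi_knots_t = np.asarray(self.psi_knots_t, dtype=float)
        self.psi_knots_mpa = np.asarray(self.psi_knots_mpa, dtype=float)
        if self.duration_s <= 0:
            raise ConfigError("duration must be > 0")
        if self.duration_s > MAX_DURATION_S:
            raise ConfigError(f"duration exceeds the {MAX_DURATION_S:.0f} s "
                              "(20 h) bench-drydown limit")
        if self.weibull_scale <= 0 or self.weibull_shape <= 0:
            raise ConfigError("Weibull scale and shape must be > 0")
        if np.any(np.diff(self.psi_knots_t) <= 0):
            raise ConfigError("psi knot times must be strictly increasing")
        if np.any(np.diff(self.psi_knots_mpa) > 0):
            raise ConfigError("psi(t) must be monotone non-increasing")
        if np.any(self.psi_knots_mpa > 0):
            raise ConfigError("psi must be <= 0 MPa")

    @classmethod
    def linear_ramp(cls, weibull_scale: float, weibull_shape: float, seed: int,
                    psi_start: float = -0.2, psi_end: float = -6.0,
                    duration_s: float = MAX_DURATION_S) -> "DrydownTruth":
        """Constant drying rate from ``psi_start`` to ``psi_end``."""
        return cls(psi_knots_t=np.array([0.0, duration_s]),
                   psi_knots_mpa=np.array([psi_start, psi_end]),
                   weibull_scale=weibull_scale, weibull_shape=weibull_shape,
                   seed=seed, duration_s=duration_s)

    def psi_true(self, t):
        """Ground-truth psi(t), clamped to the end values outside the knots."""
        return np.interp(t, self.psi_knots_t, self.psi_knots_mpa)

    def threshold_median(self) -> float:
        """Signed median of the threshold distribution: -scale * ln(2)^(1/shape)."""
        return -self.weibull_scale * np.log(2.0) ** (1.0 / self.weibull_shape)

    def threshold_mode(self) -> float:
        """Signed mode of the threshold density (requires shape > 1)."""
        k = self.weibull_shape
        if k <= 1:
            return -0.0
        return -self.weibull_scale * ((k - 1.0) / k) ** (1.0 / k)


@dataclass
class ConduitPopulation:
    """Rendered conduit population: diameters (um), 2-D centers (um), and
    per-conduit embolism thresholds (MPa, negative)."""

    diameters: np.ndarray
    positions: np.ndarray   # (n, 2) row/col centers within the region, um
    thresholds: np.ndarray  # MPa, all < 0

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        n = len(self.diameters)
        if self.positions.shape != (n, 2) or len(self.thresholds) != n:
            raise ConfigError("diameters, positions and thresholds must agree in length")
        if n and (np.any(self.diameters <= 0) or np.any(self.thresholds >= 0)):
            raise ConfigError("diameters must be > 0 and thresholds < 0")

    def __len__(self) -> int:
        return len(self.diameters)


@dataclass
class SyntheticDataset:
    """One simulated plant: population + all observable streams + truth."""

    population: ConduitPopulation
    truth: DrydownTruth
    config: SyntheticConfig
    ae_log: AEEventLog
    stack: ImageStack
    psi_measurements: list[PsiMeasurement]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _draw_positions(rng, n, region, diameters, min_separation):
    h, w = region
    margins = diameters / 2.0
    if np.any(2 * margins >= min(h, w)):
        raise GenerationError("a conduit is larger than the rendered region")
    pos = np.empty((n, 2))
    if min_separation <= 0:
        pos[:, 0] = rng.uniform(margins, h - margins)
        pos[:, 1] = rng.uniform(margins, w - margins)
        return pos
    # dart throwing with rejection; gives up rather than loop forever
    placed = 0
    attempts = 0
    max_attempts = 2000 * n
    while placed < n:
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n} conduits with min_separation="
                f"{min_separation} um in a {h}x{w} um region")
        cand = np.array([rng.uniform(margins[placed], h - margins[placed]),
                         rng.uniform(margins[placed], w - margins[placed])])
        attempts += 1
        if placed == 0 or np.all(
                np.hypot(*(pos[:placed] - cand).T)
                >= min_separation + margins[placed] + margins[:placed]):
            pos[placed] = cand
            placed += 1
    return pos


def gen_conduit_population(config: SyntheticConfig,
                           truth: DrydownTruth) -> ConduitPopulation:
    """Draw diameters from the mixture, positions within the region, and
    thresholds as -T with T ~ Weibull(scale, shape) on tension.

    With ``small_threshold_shift_mpa`` < 0 the small-class conduits get a
    constant shift toward more negative thresholds (small => more resistant,
    the pit-area-hypothesis switch).
    """
    rng_pop = _streams(truth.seed)["population"]
    rng_thr = _streams(truth.seed)["thresholds"]
    rng_pos = _streams(truth.seed)["positions"]
    n = config.n_conduits
    small = rng_pop.random(n) < config.small_class_fraction
    lo, hi = config.small_class_range
    diameters = np.where(
        small,
        rng_pop.uniform(lo, hi, size=n),
        rng_pop.lognormal(mean=np.log(config.body_median_um),
                          sigma=config.body_sigma, size=n))
    tension = truth.weibull_scale * rng_thr.weibull(truth.weibull_shape, size=n)
    tension = np.maximum(tension, 1e-6)
    thresholds = -tension
    if config.small_threshold_shift_mpa != 0.0:
        thresholds = thresholds + np.where(small, config.small_threshold_shift_mpa, 0.0)
    positions = _draw_positions(rng_pos, n, config.region_um, diameters,
                                config.min_separation_um)
    return ConduitPopulation(diameters=diameters, positions=positions,
                             thresholds=thresholds)


def gen_psi_trajectory(truth: DrydownTruth) -> PsiTimeline:
    """The ground-truth psi(t) as a piecewise-linear timeline."""
    return PsiTimeline(times=truth.psi_knots_t.copy(),
                       psis=truth.psi_knots_mpa.copy())


def first_crossing_times(thresholds, truth: DrydownTruth) -> np.ndarray:
    """First time psi(t) crosses each threshold; NaN when never crossed.

    A threshold already exceeded at t = 0 (less negative than psi(0)) is
    assigned the start time.  Handles flat psi segments by taking the
    earliest crossing segment.
    """
    tension = -np.asarray(thresholds, dtype=float)
    kt = truth.psi_knots_t
    ktension = -truth.psi_knots_mpa  # non-decreasing
    out = np.full(tension.shape, np.nan)
    out[tension <= ktension[0]] = kt[0]
    for i in range(len(kt) - 1):
        lo, hi = ktension[i], ktension[i + 1]
        sel = (tension > lo) & (tension <= hi) & np.isnan(out)
        if hi > lo:
            out[sel] = kt[i] + (tension[sel] - lo) / (hi - lo) * (kt[i + 1] - kt[i])
        else:
            out[sel] = kt[i]
    return out


def _truncnorm_amplitudes(rng, n, config):
    a = (config.detection_threshold_db - config.amplitude_mean_db) / config.amplitude_sd_db
    return sps.truncnorm.rvs(a, np.inf, loc=config.amplitude_mean_db,
                             scale=config.amplitude_sd_db, size=n, random_state=rng)


def gen_ae_stream(pop: ConduitPopulation, truth: DrydownTruth,
                  config: SyntheticConfig) -> AEEventLog:
    """One hit per conduit at its threshold-crossing time plus nuisance hits
    from an inhomogeneous Poisson process whose rate grows exponentially
    late in the drydown (so emissions never plateau)."""
    if len(pop) == 0:
        warnings.warn("empty conduit population: empty AE log", stacklevel=2)
        return AEEventLog(times=np.empty(0), amplitudes=np.empty(0),
                          plant_id="synthetic",
                          detection_threshold=config.detection_threshold_db)
    emb_times = first_crossing_times(pop.thresholds, truth)
    emb_times = emb_times[np.isfinite(emb_times)]
    rng_n = _streams(truth.seed)["nuisance"]
    rng_a = _streams(truth.seed)["amplitudes"]
    nuisance_times = np.empty(0)
    if config.nuisance_rate0_hz > 0:
        t0 = config.nuisance_onset_frac * truth.duration_s
        T = truth.duration_s
        g = config.nuisance_growth_per_s
        r0 = config.nuisance_rate0_hz
        if g > 0:
            lam_total = r0 / g * np.expm1(g * (T - t0))
        else:
            lam_total = r0 * (T - t0)
        n_nui = rng_n.poisson(lam_total)
        u = rng_n.uniform(0.0, lam_total, size=n_nui)
        if g > 0:
            nuisance_times = t0 + np.log1p(g * u / r0) / g
        else:
            nuisance_times = t0 + u / r0
    times = np.concatenate([emb_times, nuisance_times])
    order = np.argsort(times, kind="stable")
    times = times[order]
    amplitudes = _truncnorm_amplitudes(rng_a, len(times), config)
    return AEEventLog(times=times, amplitudes=amplitudes, plant_id="synthetic",
                      detection_threshold=config.detection_threshold_db)


def _render_geometry(pop: ConduitPopulation, config: SyntheticConfig):
    """Per-conduit pixel coordinates; None for sub-resolution conduits."""
    ps = config.pixel_scale_um
    shape = (int(round(config.region_um[0] / ps)), int(round(config.region_um[1] / ps)))
    coords = []
    for i in range(len(pop)):
        r_px = pop.diameters[i] / 2.0 / ps
        if np.pi * r_px ** 2 < config.min_detectable_px:
            coords.append(None)  # invisible by construction
            continue
        center = pop.positions[i] / ps
        if (center[0] - r_px < 0 or center[1] - r_px < 0
                or center[0] + r_px > shape[0] or center[1] + r_px > shape[1]):
            raise GenerationError(f"conduit {i} (d={pop.diameters[i]:.2f} um at "
                                  f"{tuple(pop.positions[i])}) lies outside the frame")
        rr, cc = draw.disk(tuple(center), r_px, shape=shape)
        coords.append((rr, cc) if len(rr) else None)
    return shape, coords


def visible_mask(pop: ConduitPopulation, config: SyntheticConfig) -> np.ndarray:
    """Which conduits render with at least ``min_detectable_px`` pixels."""
    _, coords = _render_geometry(pop, config)
    return np.array([c is not None for c in coords])


def gen_ov_stack(pop: ConduitPopulation, truth: DrydownTruth,
                 config: SyntheticConfig) -> ImageStack:
    """Render frames every ``frame_interval_s``: disks on a uniform
    background whose intensity steps by ``embolism_delta`` at the conduit's
    embolism time, plus independent Gaussian pixel noise per frame."""
    shape, coords = _render_geometry(pop, config)
    times = np.arange(0.0, truth.duration_s + 1e-9, config.frame_interval_s)
    n_frames = len(times)
    if n_frames < 2:
        raise ConfigError("duration shorter than one frame interval")
    frames = np.full((n_frames,) + shape, config.background, dtype=np.float32)
    emb_times = first_crossing_times(pop.thresholds, truth)
    for i, rc in enumerate(coords):
        if rc is None:
            continue
        rr, cc = rc
        frames[:, rr, cc] = config.background + config.lumen_offset
    for i, rc in enumerate(coords):
        if rc is None or not np.isfinite(emb_times[i]):
            continue
        rr, cc = rc
        k0 = int(np.searchsorted(times, emb_times[i], side="left"))
        if k0 < n_frames:
            frames[k0:, rr, cc] += config.embolism_delta
    if config.noise_sd > 0:
        rng = _streams(truth.seed)["noise"]
        frames += rng.normal(0.0, config.noise_sd,
                             size=frames.shape).astype(np.float32)
    return ImageStack(frames=frames, times=times,
                      pixel_scale=config.pixel_scale_um)


def gen_psi_measurements(truth: DrydownTruth,
                         config: SyntheticConfig) -> list[PsiMeasurement]:
    """Scheduled pressure-chamber readings: 2-3 plants per timepoint, each
    reading = psi(t) + independent Gaussian noise (clipped at 0)."""
    rng = _streams(truth.seed)["sampling"]
    times = np.arange(0.0, truth.duration_s + 1e-9, config.psi_sample_interval_s)
    out: list[PsiMeasurement] = []
    for j, t in enumerate(times):
        k = int(rng.choice(config.plants_per_timepoint))
        base = float(truth.psi_true(t))
        noise = rng.normal(0.0, config.psi_noise_sd_mpa, size=k) \
            if config.psi_noise_sd_mpa > 0 else np.zeros(k)
        for i in range(k):
            out.append(PsiMeasurement(time=float(t),
                                      psi=min(0.0, base + float(noise[i])),
                                      plant_id=f"t{j}_r{i}"))
    return out


def simulate(config: SyntheticConfig, truth: DrydownTruth) -> SyntheticDataset:
    """Generate a full synthetic plant (population, AE, OV, psi readings)."""
    pop = gen_conduit_population(config, truth)
    return SyntheticDataset(
        population=pop, truth=truth, config=config,
        ae_log=gen_ae_stream(pop, truth, config),
        stack=gen_ov_stack(pop, truth, config),
        psi_measurements=gen_psi_measurements(truth, config))


# ---------------------------------------------------------------------------
# On-disk dataset (same formats the analysis reads)
# ---------------------------------------------------------------------------

def write_dataset(outdir, dataset: SyntheticDataset) -> Path:
    """Write ae.csv, psi.csv, frames/ + manifest.csv and truth.json."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = dataset.ae_log
    pd.DataFrame({"time_s": log.times, "amplitude_db": log.amplitudes,
                  "plant_id": log.plant_id}).to_csv(outdir / "ae.csv", index=False)
    pd.DataFrame({"time_s": [m.time for m in dataset.psi_measurements],
                  "psi_mpa": [m.psi for m in dataset.psi_measurements],
                  "plant_id": [m.plant_id for m in dataset.psi_measurements],
                  }).to_csv(outdir / "psi.csv", index=False)
    frame_dir = outdir / "frames"
    frame_dir.mkdir(exist_ok=True)
    manifest = []
    for k, (frame, t) in enumerate(zip(dataset.stack.frames, dataset.stack.times)):
        fname = f"frame_{k:04d}.tif"
        tifffile.imwrite(frame_dir / fname, np.asarray(frame, dtype=np.float32))
        manifest.append({"frame": k, "filename": f"frames/{fname}", "time_s": t})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    truth = dataset.truth
    payload = {
        "weibull_scale": truth.weibull_scale,
        "weibull_shape": truth.weibull_shape,
        "seed": truth.seed,
        "duration_s": truth.duration_s,
        "psi_knots_t": truth.psi_knots_t.tolist(),
        "psi_knots_mpa": truth.psi_knots_mpa.tolist(),
        "threshold_median_mpa": truth.threshold_median(),
        "threshold_mode_mpa": truth.threshold_mode(),
        "config": asdict(dataset.config),
        "n_conduits": len(dataset.population),
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))
    return outdir
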