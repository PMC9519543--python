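"""Synthetic binding scenes for single-particle interferometric microarrays.

The simulator produces the ground truth that the detection / tracking /
quantification stages are validated against: Poisson binding-event streams
whose rate follows the diffusion-limited low-concentration scaling
``rate = k * (c / c_ref)**(2/3)``, exponential dwell times with a permanent
fraction, and rendered image stacks (time-lapse movies or defocus z-stacks)
with diffraction-limited Gaussian particle images and shot noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .frames import FrameStack

__all__ = [
    "SimulationConfig",
    "SpotRegion",
    "GroundTruthEvent",
    "CalibrationSet",
    "binding_rate",
    "sample_events",
    "render_timelapse",
    "render_zstack",
    "make_calibration_dataset",
    "cumulative_events",
    "planted_lod",
    "nonspecific_rate_for_lod",
    "events_to_frame",
]

#: Default concentration grid: 100 aM to 1 pM in decade steps.
DEFAULT_CONCENTRATIONS = (1e-16, 1e-15, 1e-14, 1e-13, 1e-12)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic assay.

    All physical quantities must be strictly positive except
    ``permanent_fraction`` which lies in [0, 1].

    Attributes
    ----------
    image_shape : (int, int)
        Frame height and width in pixels.
    pixel_pitch : float
        Micrometres per pixel at the sample plane.
    frame_interval : float
        Seconds between frames in kinetic (time-lapse) mode.
    z_step : float
        Micrometres between focus planes in endpoint (z-stack) mode.
    psf_sigma : float
        Gaussian point-spread sigma in pixels.
    particle_contrast : float
        Peak particle amplitude relative to a background level of 1.0.
    background_level : float
        Mean background grayscale value.
    shot_noise_scale : float
        Per-pixel Gaussian noise SD as a fraction of the background level.
    rate_constant : float
        Binding events per hour per spot at the reference concentration.
    c_ref : float
        Reference concentration (molar). Fixed at 1 fM so rate constants
        stay human-scale.
    scaling_exponent : float
        Exponent of the concentration dependence of the binding rate;
        2/3 for diffusion-limited sheet-density scaling.
    mean_dwell_time : float
        Mean dwell (seconds) of transient binders; dwells are exponential.
    permanent_fraction : float
        Probability that a binder never debinds within the experiment.
    nonspecific_rate : float
        Concentration-independent event rate (events/h/spot); this is the
        blank / control-spot background rate.
    duration : float
        Total incubation time simulated, seconds.
    defocus_period, defocus_width : float
        Parameters (micrometres) of the defocus contrast curve
        ``a(z) = contrast * sin(2*pi*z/period) * exp(-z^2 / (2*width^2))``.
    z_range : (float, float)
        Focus scan range in micrometres, relative to best focus.
    concentrations : tuple of float
        Default calibration grid (molar).
    flow_rate_ul_min : float
        Sample flow rate, recorded as metadata only (transport physics is
        not simulated).
    rng_seed : int
        Seed for all randomness in this configuration.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_pitch: float = 0.5
    frame_interval: float = 10.0
    z_step: float = 0.25
    psf_sigma: float = 1.5
    particle_contrast: float = 0.15
    background_level: float = 1000.0
    shot_noise_scale: float = 0.01
    rate_constant: float = 170.0
    c_ref: float = 1e-15
    scaling_exponent: float = 2.0 / 3.0
    mean_dwell_time: float = 300.0
    permanent_fraction: float = 0.25
    nonspecific_rate: float = 2.0
    duration: float = 1800.0
    defocus_period: float = 2.0
    defocus_width: float = 1.0
    z_range: tuple[float, float] = (-2.0, 2.0)
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    flow_rate_ul_min: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "pixel_pitch": self.pixel_pitch,
            "frame_interval": self.frame_interval,
            "z_step": self.z_step,
            "psf_sigma": self.psf_sigma,
            "particle_contrast": self.particle_contrast,
            "background_level": self.background_level,
            "rate_constant": self.rate_constant,
            "c_ref": self.c_ref,
            "scaling_exponent": self.scaling_exponent,
            "mean_dwell_time": self.mean_dwell_time,
            "duration": self.duration,
            "defocus_period": self.defocus_period,
            "defocus_width": self.defocus_width,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.shot_noise_scale < 0:
            raise ValueError("shot_noise_scale must be >= 0")
        if self.nonspecific_rate < 0:
            raise ValueError("nonspecific_rate must be >= 0")
        if not 0.0 <= self.permanent_fraction <= 1.0:
            raise ValueError("permanent_fraction must lie in [0, 1]")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be (h, w) with h, w >= 8")
        if self.z_range[1] <= self.z_range[0]:
            raise ValueError("z_range must be increasing")
        self.image_shape = tuple(int(v) for v in self.image_shape)
        self.concentrations = tuple(float(c) for c in self.concentrations)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SpotRegion:
    """A circular probe spot in pixel coordinates."""

    spot_id: str
    cx: float
    cy: float
    radius: float
    probe_label: str = "target"

    def contains(self, x: float, y: float) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2


def default_spot(config: SimulationConfig, spot_id: str = "spot_0") -> SpotRegion:
    """Single spot centered in the frame, radius 0.35 * min(image side)."""
    h, w = config.image_shape
    return SpotRegion(spot_id, (w - 1) / 2.0, (h - 1) / 2.0, 0.35 * min(h, w))


@dataclass(frozen=True)
class GroundTruthEvent:
    """One planted binding event.

    ``t_unbind`` is ``inf`` for permanent binders; otherwise
    ``t_unbind > t_bind``.
    """

    event_id: int
    spot_id: str
    x: float
    y: float
    t_bind: float
    t_unbind: float

    @property
    def permanent(self) -> bool:
        return math.isinf(self.t_unbind)


def binding_rate(config: SimulationConfig, concentration: float) -> float:
    """Specific binding rate (events/hour/spot) at a given molarity.

    Follows ``k * (c / c_ref)**exponent`` at every concentration; the 2/3
    exponent is the diffusion-limited low-concentration law.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if concentration == 0:
        return 0.0
    return config.rate_constant * (concentration / config.c_ref) ** config.scaling_exponent


def sample_events(
    config: SimulationConfig,
    spot: SpotRegion,
    concentration: float,
    rng: np.random.Generator | None = None,
    *,
    include_nonspecific: bool = True,
) -> list[GroundTruthEvent]:
    """Draw a homogeneous Poisson stream of binding events on one spot.

    The total rate is ``binding_rate(c) + nonspecific_rate`` (the latter
    only when ``include_nonspecific``). Each event gets a uniform position
    in the spot disc, a uniform arrival time in ``[0, duration)``, and an
    exponential dwell of mean ``mean_dwell_time`` unless it is permanent
    (probability ``permanent_fraction``).
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if rng is None:
        rng = config.rng()
    rate = binding_rate(config, concentration)
    if include_nonspecific:
        rate += config.nonspecific_rate
    duration_h = config.duration / 3600.0
    n = int(rng.poisson(rate * duration_h))
    if n == 0:
        return []
    t_bind = np.sort(rng.uniform(0.0, config.duration, size=n))
    r = spot.radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    xs = spot.cx + r * np.cos(theta)
    ys = spot.cy + r * np.sin(theta)
    permanent = rng.uniform(size=n) < config.permanent_fraction
    dwell = rng.exponential(config.mean_dwell_time, size=n)
    t_unbind = np.where(permanent, np.inf, t_bind + dwell)
    return [
        GroundTruthEvent(i, spot.spot_id, float(xs[i]), float(ys[i]),
                         float(t_bind[i]), float(t_unbind[i]))
        for i in range(n)
    ]


def _add_gaussian(frame: np.ndarray, x: float, y: float, amplitude: float,
                  sigma: float) -> None:
    """Add an isotropic Gaussian bump in-place, truncated at 4 sigma."""
    h, w = frame.shape
    r = int(math.ceil(4.0 * sigma))
    x0, y0 = int(round(x)), int(round(y))
    xs = np.arange(max(0, x0 - r), min(w, x0 + r + 1))
    ys = np.arange(max(0, y0 - r), min(h, y0 + r + 1))
    if xs.size == 0 or ys.size == 0:
        return
    gx = np.exp(-((xs - x) ** 2) / (2.0 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2.0 * sigma**2))
    frame[np.ix_(ys, xs)] += amplitude * np.outer(gy, gx)


def render_timelapse(
    config: SimulationConfig,
    events: list[GroundTruthEvent],
    rng: np.random.Generator | None = None,
) -> FrameStack:
    """Render events into a kinetic movie.

    Frame ``n`` (time ``n * frame_interval``) shows a Gaussian bump of
    amplitude ``particle_contrast * background_level`` at every event with
    ``t_bind <= t < t_unbind``, on top of the background, plus per-pixel
    Gaussian noise. An empty event list yields a blank movie.
    """
    if rng is None:
        rng = config.rng()
    h, w = config.image_shape
    n_frames = max(1, int(round(config.duration / config.frame_interval)))
    times = np.arange(n_frames) * config.frame_interval
    bg = config.background_level
    frames = np.full((n_frames, h, w), bg, dtype=float)
    amp = config.particle_contrast * bg
    for ev in events:
        if not (0.0 <= ev.x < w and 0.0 <= ev.y < h):
            raise ValueError(f"event {ev.event_id} outside image bounds")
        if ev.t_bind < 0 or ev.t_bind > config.duration:
            raise ValueError(f"event {ev.event_id} outside duration")
        first = int(np.searchsorted(times, ev.t_bind, side="left"))
        last = int(np.searchsorted(times, ev.t_unbind, side="left"))
        for fi in range(first, min(last, n_frames)):
            _add_gaussian(frames[fi], ev.x, ev.y, amp, config.psf_sigma)
    if config.shot_noise_scale > 0:
        frames += rng.normal(0.0, config.shot_noise_scale * bg, frames.shape)
    return FrameStack(frames, "time", times, config.pixel_pitch,
                      meta={"flow_rate_ul_min": config.flow_rate_ul_min})


def defocus_amplitude(config: SimulationConfig, z: np.ndarray) -> np.ndarray:
    """Relative particle contrast as a function of defocus ``z`` (um).

    Antisymmetric about best focus: the interferometric particle signature
    flips sign across the focal plane.
    """
    z = np.asarray(z, dtype=float)
    return (config.particle_contrast
            * np.sin(2.0 * np.pi * z / config.defocus_period)
            * np.exp(-(z**2) / (2.0 * config.defocus_width**2)))


def render_zstack(
    config: SimulationConfig,
    particles: list[tuple[float, float]],
    rng: np.random.Generator | None = None,
) -> FrameStack:
    """Render surface-bound particles into an endpoint defocus z-stack.

    Particle amplitude varies across focus as ``defocus_amplitude``, so the
    per-pixel max-min across the stack rises above the noise floor at
    particle sites and stays at the noise floor elsewhere.
    """
    if rng is None:
        rng = config.rng()
    h, w = config.image_shape
    z0, z1 = config.z_range
    z = np.arange(z0, z1 + config.z_step / 2.0, config.z_step)
    if len(z) < 3:
        raise ValueError("z_range/z_step give fewer than 3 planes")
    bg = config.background_level
    amp = defocus_amplitude(config, z) * bg
    frames = np.full((len(z), h, w), bg, dtype=float)
    for (x, y) in particles:
        if not (0.0 <= x < w and 0.0 <= y < h):
            raise ValueError(f"particle at ({x}, {y}) outside image bounds")
        for zi in range(len(z)):
            _add_gaussian(frames[zi], x, y, amp[zi], config.psf_sigma)
    if config.shot_noise_scale > 0:
        frames += rng.normal(0.0, config.shot_noise_scale * bg, frames.shape)
    return FrameStack(frames, "z", z, config.pixel_pitch)


def cumulative_events(events: list[GroundTruthEvent], times: np.ndarray) -> np.ndarray:
    """Cumulative number of binding events at each sample time.

    Debinding never decrements the count (total-binding convention).
    """
    t_bind = np.sort([ev.t_bind for ev in events])
    return np.searchsorted(t_bind, np.asarray(times, dtype=float), side="right")


def events_to_frame(events: list[GroundTruthEvent]) -> pd.DataFrame:
    """Ground-truth events as a table (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "spot_id": ev.spot_id,
                "x": ev.x,
                "y": ev.y,
                "t_bind": ev.t_bind,
                "t_unbind": ev.t_unbind,
            }
            for ev in events
        ],
        columns=["event_id", "spot_id", "x", "y", "t_bind", "t_unbind"],
    )


@dataclass
class CalibrationSet:
    """Synthetic (concentration, binding rate) points with blank statistics.

    ``rates`` has one row per replicate: concentration (molar), replicate
    index, events counted, and the rate in events/hour. ``blank_rates`` are
    the replicate rates at zero target concentration (nonspecific binding
    only).
    """

    rates: pd.DataFrame
    blank_rates: np.ndarray
    config: SimulationConfig
    duration_h: float = field(init=False)

    def __post_init__(self) -> None:
        self.duration_h = self.config.duration / 3600.0

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.rates["concentration"].unique())

    def mean_rates(self) -> pd.DataFrame:
        g = self.rates.groupby("concentration")["rate_per_h"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out.columns = ["concentration", "rate_mean", "rate_sd", "n"]
        return out

    @property
    def blank_mean(self) -> float:
        return float(np.mean(self.blank_rates)) if len(self.blank_rates) else 0.0

    @property
    def blank_sd(self) -> float:
        if len(self.blank_rates) < 2:
            return 0.0
        return float(np.std(self.blank_rates, ddof=1))

    def true_rate(self, concentration: float) -> float:
        return binding_rate(self.config, concentration)


def make_calibration_dataset(
    config: SimulationConfig,
    concentrations: tuple[float, ...] | None = None,
    replicates: int = 16,
    blank_replicates: int = 16,
    seed: int | None = None,
) -> CalibrationSet:
    """Simulate a full calibration: replicate spots per concentration + blanks.

    Rates are taken from the event model as events counted / incubation time;
    blanks are spots exposed to zero target concentration, so they only see
    the configured nonspecific rate.
    """
    if concentrations is None:
        concentrations = config.concentrations
    concentrations = tuple(float(c) for c in concentrations)
    if len(concentrations) < 2:
        raise ValueError("need at least 2 concentrations plus blanks")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    spot = default_spot(config)
    duration_h = config.duration / 3600.0
    rows = []
    for c in concentrations:
        for rep in range(replicates):
            events = sample_events(config, spot, c, rng)
            rows.append(
                {"concentration": c, "replicate": rep,
                 "n_events": len(events),
                 "rate_per_h": len(events) / duration_h}
            )
    blanks = np.array(
        [len(sample_events(config, spot, 0.0, rng)) / duration_h
         for _ in range(blank_replicates)]
    )
    return CalibrationSet(pd.DataFrame(rows), blanks, config)


def blank_rate_sd(config: SimulationConfig) -> float:
    """Counting-noise SD of a blank replicate's rate estimate (events/h)."""
    duration_h = config.duration / 3600.0
    return math.sqrt(config.nonspecific_rate / duration_h)


def planted_lod(config: SimulationConfig) -> float:
    """Concentration where the true rate law crosses blank mean + 3 SD.

    The blank SD is the Poisson counting noise of a single replicate,
    ``sqrt(nonspecific_rate / duration_h)``, i.e. the expected scatter of
    measured blank rates. This is the ground-truth kinetic LOD implied by
    the configuration.
    """
    threshold = config.nonspecific_rate + 3.0 * blank_rate_sd(config)
    if threshold <= 0:
        raise ValueError("nonspecific_rate is 0: planted LOD undefined")
    return config.c_ref * (threshold / config.rate_constant) ** (
        1.0 / config.scaling_exponent
    )


def nonspecific_rate_for_lod(config: SimulationConfig, lod: float) -> float:
    """Nonspecific rate (events/h) that plants a given kinetic LOD.

    Inverts ``planted_lod``: solves
    ``lam + 3*sqrt(lam/T) = k*(lod/c_ref)**exponent`` for ``lam``.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    threshold = config.rate_constant * (lod / config.c_ref) ** config.scaling_exponent
    t_h = config.duration / 3600.0
    # quadratic in s = sqrt(lam): s^2 + (3/sqrt(T)) s - threshold = 0
    b = 3.0 / math.sqrt(t_h)
    s = (-b + math.sqrt(b * b + 4.0 * threshold)) / 2.0
    return s * s
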