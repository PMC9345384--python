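"""Dynamic digital thorax phantom for self-gated lung-function microCT.

The phantom is a desk-scale stand-in for a free-breathing, anesthetized mouse
in a rotating-gantry microCT: an elliptical soft-tissue body containing two
lung ellipses, a cardiac region and a spine, all defined in an axial (x, y)
cross-section and extruded along the craniocaudal axis z. Breathing moves the
diaphragm dome caudally and expands the chest; the heart modulates its
attenuation at a fixed rate. Each projection frame is a genuine 2D image
(rows = z, columns = detector coordinate u) computed row-by-row with the
closed-form Radon transform of uniform ellipses, converted to transmitted
intensity, scaled by a slow non-periodic tube-intensity drift, and degraded
with Poisson photon noise.

Every acquisition carries its ground-truth motion parameters in
``ProjectionSeries.metadata``, so downstream trace extraction, expiration
fitting and gated reconstruction can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidParameterError

__all__ = [
    "Ellipse",
    "Region",
    "PhantomConfig",
    "BreathingParams",
    "AcquisitionConfig",
    "ProjectionSeries",
    "breathing_waveform",
    "breath_schedule",
    "waveform_on_schedule",
    "render_thorax_frame",
    "generate_acquisition",
    "tube_drift",
    "reference_slice_z",
    "end_expiration_slice",
    "rasterize_body_mask",
    "rasterize_lung_mask",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (cx, cy) and semi-axes (a, b), all in mm."""

    cx: float
    cy: float
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class Region:
    """An ellipse together with its baseline attenuation (1/mm)."""

    shape: Ellipse
    attenuation: float


def _default_lungs() -> tuple[Region, ...]:
    return (
        Region(Ellipse(-3.2, -0.6, 2.6, 3.4), 0.008),
        Region(Ellipse(3.2, -0.6, 2.6, 3.4), 0.008),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Anatomy and grid of the thorax phantom.

    Attenuation defaults approximate soft tissue / inflated lung / bone at the
    ~60 keV effective energy of a 90 kV microCT spectrum. The axial layout is
    expressed as fractions of the axial field of view (``grid_size *
    pixel_size``): lung tissue spans from an apex taper down to a diaphragm
    dome whose base sits at ``diaphragm_frac`` at end expiration and moves
    caudally by ``diaphragm_amplitude`` times the lung height per unit breath
    phase.
    """

    body: Ellipse = Ellipse(0.0, 0.0, 7.3, 6.6)
    lung_regions: tuple[Region, ...] = field(default_factory=_default_lungs)
    diaphragm_amplitude: float = 0.2
    cardiac_region: Ellipse = Ellipse(0.5, 0.9, 2.1, 2.5)
    cardiac_amplitude: float = 0.08
    bone_region: Ellipse = Ellipse(0.0, 4.8, 0.7, 0.7)
    attenuation_soft_tissue: float = 0.022
    attenuation_lung: float = 0.008
    attenuation_bone: float = 0.06
    grid_size: int = 192
    pixel_size: float = 0.1
    chest_expansion: float = 0.005
    lung_air_modulation: float = 0.02
    apex_frac: float = 0.18
    apex_taper_frac: float = 0.05
    diaphragm_frac: float = 0.60
    dome_width_frac: float = 0.10
    heart_span_frac: tuple[float, float] = (0.28, 0.55)

    def __post_init__(self):
        if self.grid_size <= 0:
            raise ConfigurationError("grid_size must be positive")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if not (
            self.attenuation_lung
            < self.attenuation_soft_tissue
            < self.attenuation_bone
        ):
            raise ConfigurationError(
                "attenuations must satisfy lung < soft tissue < bone"
            )
        if self.diaphragm_amplitude < 0 or self.cardiac_amplitude < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        half_fov = 0.5 * self.grid_size * self.pixel_size
        b = self.body
        if (
            abs(b.cx) + b.a > half_fov
            or abs(b.cy) + b.b > half_fov
        ):
            raise ConfigurationError("grid too small to contain the body")

    # -- axial geometry helpers -------------------------------------------
    @property
    def axial_extent(self) -> float:
        """Craniocaudal extent of the frame, mm."""
        return self.grid_size * self.pixel_size

    @property
    def z_apex(self) -> float:
        return self.apex_frac * self.axial_extent

    @property
    def z_diaphragm_rest(self) -> float:
        """Diaphragm dome base at end expiration (breath phase 0), mm."""
        return self.diaphragm_frac * self.axial_extent

    @property
    def lung_height(self) -> float:
        return self.z_diaphragm_rest - self.z_apex

    def z_diaphragm(self, breath_phase):
        return (
            self.z_diaphragm_rest
            + self.diaphragm_amplitude * np.asarray(breath_phase) * self.lung_height
        )

    def z_rows(self) -> np.ndarray:
        """z coordinate (mm) of every frame row; row 0 is cranial."""
        return (np.arange(self.grid_size) + 0.5) * self.pixel_size

    def lung_occupancy(self, z, breath_phase):
        """Fraction of the lung cross-section occupied by lung tissue at z.

        0 above the apex taper and below the diaphragm dome, 1 in mid-lung;
        across the dome the occupancy ramps linearly (a partial-volume fade
        standing in for the dome's curvature). The dome base descends with
        breath phase, so the occupancy at a fixed z near the interface grows
        monotonically — and, while the ramp stays inside an ROI, the summed
        line integral is exactly linear in the breath phase, which is what
        makes the expiration decay constant recoverable from the trace.
        """
        z = np.asarray(z, dtype=float)
        w_apex = max(self.apex_taper_frac * self.axial_extent, 1e-9)
        w_dome = max(self.dome_width_frac * self.axial_extent, 1e-9)
        apex = np.clip((z - self.z_apex) / w_apex, 0.0, 1.0)
        dome = np.clip((self.z_diaphragm(breath_phase) - z) / w_dome, 0.0, 1.0)
        return apex * dome

    def heart_rows(self, z) -> np.ndarray:
        lo, hi = self.heart_span_frac
        z = np.asarray(z, dtype=float)
        return (z >= lo * self.axial_extent) & (z <= hi * self.axial_extent)


@dataclass(frozen=True)
class BreathingParams:
    """Ground-truth breathing pattern: I0*exp(-k*tau^2)+c expirations.

    The default period of 1.4 s matches isoflurane anesthesia titrated to
    ~0.7 Hz; inspirations are short half-sine rises. ``period_jitter`` is the
    fractional standard deviation of per-cycle period variation applied by
    the acquisition-level breath schedule (the pure waveform stays periodic).
    """

    period: float = 1.4
    inspiration_duration: float = 0.2
    k_true: float = 2.0
    I0_true: float = 1.0
    c_true: float = 0.0
    period_jitter: float = 0.03

    def __post_init__(self):
        if self.period <= 0:
            raise InvalidParameterError("breathing period must be positive")
        if not 0 < self.inspiration_duration < self.period:
            raise InvalidParameterError(
                "inspiration_duration must lie strictly inside the period"
            )
        if self.k_true <= 0:
            raise InvalidParameterError("k_true must be positive")
        if self.period_jitter < 0:
            raise InvalidParameterError("period_jitter must be non-negative")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scanner protocol: frame count, rotation, timing, drift and noise.

    Defaults reproduce the rotational CT protocol (1028 frames over 720 deg
    in 34 s); ``planar()`` gives the stationary 1024-frame protocol. The tube
    drift is a linear ramp times a sinusoid with a non-integer number of
    cycles over the scan, i.e. deliberately not periodic in one rotation.
    ``photon_count=None`` disables photon noise (ideal detector).
    """

    n_frames: int = 1028
    total_rotation: float = 720.0
    total_time: float = 34.0
    heart_rate_bpm: float = 470.0
    photon_count: float | None = 5000.0
    drift_amplitude: float = 0.03
    drift_cycles: float = 2.7
    drift_slope: float = 0.05
    drift_phase: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be at least 2")
        if self.total_time <= 0:
            raise ConfigurationError("total_time must be positive")
        rot = self.total_rotation
        if not (rot == 0 or (rot > 0 and math.isclose(rot % 360.0, 0.0, abs_tol=1e-9))):
            raise ConfigurationError(
                "total_rotation must be 0 (planar) or a positive multiple of 360"
            )
        if self.photon_count is not None and self.photon_count <= 0:
            raise ConfigurationError("photon_count must be positive or None")

    @classmethod
    def planar(cls, **overrides) -> "AcquisitionConfig":
        """The planar cinematic (XLF) protocol: 1024 frames, no rotation."""
        defaults = dict(n_frames=1024, total_rotation=0.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ProjectionSeries:
    """Time-ordered projection frames with per-frame angle and timestamp."""

    frames: np.ndarray  # (n_frames, n_rows, n_det), non-negative intensities
    angles: np.ndarray  # degrees
    times: np.ndarray  # seconds
    pixel_size: float  # mm, detector sampling
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.angles = np.asarray(self.angles, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n = len(self.frames)
        if not (len(self.angles) == len(self.times) == n):
            raise ConfigurationError("angles, times and frames must align")
        if n >= 2:
            if np.any(np.diff(self.angles) < -1e-9):
                raise ConfigurationError("angles must be monotone non-decreasing")
            if np.any(np.diff(self.times) <= 0):
                raise ConfigurationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_rotation(self) -> float:
        meta = self.metadata.get("acquisition", {})
        if "total_rotation" in meta:
            return float(meta["total_rotation"])
        return float(self.angles[-1] - self.angles[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


# ---------------------------------------------------------------------------
# breathing waveform
# ---------------------------------------------------------------------------

def _cycle_value(tau, prev_period, params: BreathingParams):
    """Waveform value at time tau since inspiration onset of one cycle."""
    p = params
    tau = np.asarray(tau, dtype=float)
    prev_period = np.asarray(prev_period, dtype=float)
    d = p.inspiration_duration
    peak = p.c_true + p.I0_true
    # end-of-expiration value of the preceding cycle: the rise starts there,
    # keeping the waveform continuous across the cycle wrap
    f0 = p.I0_true * np.exp(-p.k_true * (prev_period - d) ** 2) + p.c_true
    rise = f0 + (peak - f0) * np.sin(0.5 * np.pi * np.minimum(tau, d) / d)
    decay = p.I0_true * np.exp(-p.k_true * (tau - d) ** 2) + p.c_true
    return np.where(tau < d, rise, decay)


def breathing_waveform(t, params: BreathingParams):
    """Strictly periodic breathing waveform f(t).

    Each cycle starts at an inspiration onset (t = 0 mod period): a monotone
    half-sine rise of ``inspiration_duration`` up to the peak value
    ``c_true + I0_true``, followed by the expiration decay
    ``I0_true * exp(-k_true * tau^2) + c_true`` with tau the time since the
    peak. Continuous at the peak and (by construction of the rise start) at
    the cycle wrap.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be non-negative")
    tau = np.mod(t, params.period)
    return _cycle_value(tau, params.period, params)


def breath_schedule(
    params: BreathingParams, total_time: float, rng: np.random.Generator
) -> np.ndarray:
    """Seeded inspiration-onset times covering [0, total_time].

    The first onset is drawn uniformly within one period before t=0; cycle
    lengths are jittered by ``period_jitter`` (fractional sigma, truncated at
    twice the inspiration duration) to emulate anesthesia breathing-rate
    variability. Returns onsets including one cycle of padding on each side.
    """
    p = params
    onsets = [-p.period - rng.uniform(0.0, p.period)]
    floor = 2.0 * p.inspiration_duration
    while onsets[-1] < total_time + p.period:
        step = p.period * (1.0 + p.period_jitter * rng.standard_normal())
        onsets.append(onsets[-1] + max(step, floor))
    return np.asarray(onsets)


def waveform_on_schedule(t, onsets: np.ndarray, params: BreathingParams):
    """Evaluate the breathing waveform on a jittered onset schedule."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(onsets, t, side="right") - 1
    if np.any(idx < 1) or np.any(idx >= len(onsets) - 1):
        raise InvalidParameterError("schedule does not cover the requested times")
    tau = t - onsets[idx]
    prev_period = onsets[idx] - onsets[idx - 1]
    return _cycle_value(tau, prev_period, params)


def breath_phase_from_value(values, params: BreathingParams):
    """Map waveform values to the geometric breath phase in [0, 1]."""
    return np.clip(
        (np.asarray(values, dtype=float) - params.c_true) / params.I0_true, 0.0, 1.0
    )


# ---------------------------------------------------------------------------
# rendering (per-pixel rasterization of one axial slice)
# ---------------------------------------------------------------------------

def reference_slice_z(cfg: PhantomConfig) -> float:
    """Default axial position: mid-dome at end expiration (the interface)."""
    return cfg.z_diaphragm_rest - 0.5 * cfg.dome_width_frac * cfg.axial_extent


def _grid_coords(grid_side: int, voxel_size: float):
    c = (np.arange(grid_side) - (grid_side - 1) / 2.0) * voxel_size
    return np.meshgrid(c, c)  # x varies along columns, y along rows


def _inside(e: Ellipse, x, y, scale: float = 1.0) -> np.ndarray:
    if scale <= 0:
        return np.zeros(np.broadcast(x, y).shape, dtype=bool)
    return ((x - e.cx) / (e.a * scale)) ** 2 + ((y - e.cy) / (e.b * scale)) ** 2 <= 1.0


def render_thorax_frame(
    cfg: PhantomConfig,
    breath_phase: float,
    cardiac_phase: float,
    z: float | None = None,
    grid_side: int | None = None,
    voxel_size: float | None = None,
) -> np.ndarray:
    """Rasterize the attenuation map (1/mm) of one axial slice.

    Composition is additive over ellipse regions: body soft tissue, lung
    deltas (scaled in-plane by the axial lung profile and chest expansion,
    with attenuation dropping as air fills), a cardiac attenuation
    modulation and a bone delta. Outside the body the map is zero.
    """
    if not (np.isfinite(breath_phase) and np.isfinite(cardiac_phase)):
        raise InvalidParameterError("phases must be finite")
    if z is None:
        z = reference_slice_z(cfg)
    grid_side = cfg.grid_size if grid_side is None else grid_side
    voxel_size = cfg.pixel_size if voxel_size is None else voxel_size
    x, y = _grid_coords(grid_side, voxel_size)

    mu = np.zeros((grid_side, grid_side))
    mu[_inside(cfg.body, x, y)] = cfg.attenuation_soft_tissue

    occupancy = float(cfg.lung_occupancy(z, breath_phase))
    scale = 1.0 + cfg.chest_expansion * breath_phase
    for region in cfg.lung_regions:
        mu_lung = region.attenuation * (
            1.0 - cfg.lung_air_modulation * breath_phase
        )
        mu[_inside(region.shape, x, y, scale)] += occupancy * (
            mu_lung - cfg.attenuation_soft_tissue
        )

    if cfg.heart_rows(z):
        delta = (
            cfg.attenuation_soft_tissue
            * cfg.cardiac_amplitude
            * math.sin(2.0 * math.pi * cardiac_phase)
        )
        mu[_inside(cfg.cardiac_region, x, y)] += delta

    mu[_inside(cfg.bone_region, x, y)] += (
        cfg.attenuation_bone - cfg.attenuation_soft_tissue
    )
    return np.clip(mu, 0.0, None)


def rasterize_body_mask(
    cfg: PhantomConfig, grid_side: int, voxel_size: float
) -> np.ndarray:
    x, y = _grid_coords(grid_side, voxel_size)
    return _inside(cfg.body, x, y)


def rasterize_lung_mask(
    cfg: PhantomConfig,
    grid_side: int,
    voxel_size: float,
    breath_phase: float = 0.0,
    z: float | None = None,
) -> np.ndarray:
    if z is None:
        z = reference_slice_z(cfg)
    x, y = _grid_coords(grid_side, voxel_size)
    mask = np.zeros((grid_side, grid_side), dtype=bool)
    if float(cfg.lung_occupancy(z, breath_phase)) <= 0:
        return mask
    scale = 1.0 + cfg.chest_expansion * breath_phase
    for region in cfg.lung_regions:
        mask |= _inside(region.shape, x, y, scale)
    return mask


def end_expiration_slice(
    cfg: PhantomConfig, grid_side: int | None = None, voxel_size: float | None = None
) -> np.ndarray:
    """Ground-truth end-expiration attenuation map at the interface slice."""
    return render_thorax_frame(
        cfg, 0.0, 0.0, grid_side=grid_side, voxel_size=voxel_size
    )


# ---------------------------------------------------------------------------
# analytic parallel-beam projection
# ---------------------------------------------------------------------------

def _ellipse_chord(e: Ellipse, cos_a: float, sin_a: float, u, scale=1.0):
    """Closed-form Radon transform of a unit-density uniform ellipse.

    ``u`` is the detector coordinate (mm) along the axis perpendicular to the
    ray direction; ``scale`` (scalar or column vector) scales both semi-axes
    about the ellipse center. Returns chord lengths (mm).
    """
    u0 = e.cx * cos_a + e.cy * sin_a
    s2 = (e.a * cos_a) ** 2 + (e.b * sin_a) ** 2
    scale = np.asarray(scale, dtype=float)
    arg = np.clip(scale**2 * s2 - (u - u0) ** 2, 0.0, None)
    return 2.0 * e.a * e.b / s2 * np.sqrt(arg)


def _detector_coords(cfg: PhantomConfig) -> np.ndarray:
    n = cfg.grid_size
    return (np.arange(n) - (n - 1) / 2.0) * cfg.pixel_size


def project_line_integrals(
    cfg: PhantomConfig,
    angle_deg: float,
    breath_phase: float,
    cardiac_phase: float,
) -> np.ndarray:
    """Line-integral frame (rows = z, cols = detector u) at one gantry angle."""
    phi = math.radians(angle_deg)
    cos_a, sin_a = math.cos(phi), math.sin(phi)
    u = _detector_coords(cfg)
    z = cfg.z_rows()

    line = np.tile(
        cfg.attenuation_soft_tissue * _ellipse_chord(cfg.body, cos_a, sin_a, u),
        (cfg.grid_size, 1),
    )
    line += (cfg.attenuation_bone - cfg.attenuation_soft_tissue) * _ellipse_chord(
        cfg.bone_region, cos_a, sin_a, u
    )

    occupancy = cfg.lung_occupancy(z, breath_phase)[:, None]
    scale = 1.0 + cfg.chest_expansion * breath_phase
    for region in cfg.lung_regions:
        mu_lung = region.attenuation * (1.0 - cfg.lung_air_modulation * breath_phase)
        line += (
            occupancy
            * (mu_lung - cfg.attenuation_soft_tissue)
            * _ellipse_chord(region.shape, cos_a, sin_a, u[None, :], scale)
        )

    delta = (
        cfg.attenuation_soft_tissue
        * cfg.cardiac_amplitude
        * math.sin(2.0 * math.pi * cardiac_phase)
    )
    if delta != 0.0:
        heart = _ellipse_chord(cfg.cardiac_region, cos_a, sin_a, u)
        line[cfg.heart_rows(z), :] += delta * heart

    return np.clip(line, 0.0, None)


def tube_drift(t, acq: AcquisitionConfig):
    """Slow multiplicative tube-intensity drift: ramp x non-periodic sinusoid."""
    t = np.asarray(t, dtype=float)
    ramp = 1.0 + acq.drift_slope * t / acq.total_time
    wave = 1.0 + acq.drift_amplitude * np.sin(
        2.0 * math.pi * acq.drift_cycles * t / acq.total_time + acq.drift_phase
    )
    return ramp * wave


def generate_acquisition(
    cfg: PhantomConfig,
    acq: AcquisitionConfig,
    breathing: BreathingParams | None = None,
) -> ProjectionSeries:
    """Simulate a full rotational or planar acquisition.

    Frame i is taken at time ``t_i = i * total_time / (n_frames - 1)`` and
    angle ``alpha_i = i * total_rotation / n_frames`` (endpoint-exclusive,
    so that frames i and i + n_frames/2 of a two-rotation scan share their
    projection angle exactly — the property the gating pairing relies on);
    intensity is
    ``photon_count * drift(t_i) * exp(-line integral)`` with Poisson noise
    (noiseless transmission if ``photon_count`` is None). Ground truth —
    breath schedule, per-frame phases, drift and all configs — is stored in
    ``metadata``. Identical seed and configs give bit-identical output.
    """
    if breathing is None:
        breathing = BreathingParams()
    rng = np.random.default_rng(acq.seed)
    n = acq.n_frames
    times = np.arange(n) * acq.total_time / (n - 1)
    angles = np.arange(n) * acq.total_rotation / n

    onsets = breath_schedule(breathing, acq.total_time, rng)
    values = waveform_on_schedule(times, onsets, breathing)
    phases = breath_phase_from_value(values, breathing)
    cardiac = np.mod(times * acq.heart_rate_bpm / 60.0, 1.0)
    drift = tube_drift(times, acq)

    frames = np.empty((n, cfg.grid_size, cfg.grid_size), dtype=np.float32)
    for i in range(n):
        line = project_line_integrals(cfg, angles[i], phases[i], cardiac[i])
        expected = drift[i] * np.exp(-line)
        if acq.photon_count is None:
            frames[i] = expected
        else:
            frames[i] = rng.poisson(acq.photon_count * expected)

    visible = (onsets >= 0) & (onsets <= acq.total_time)
    metadata = {
        "acquisition": asdict(acq),
        "phantom": asdict(cfg),
        "breathing": asdict(breathing),
        "ground_truth": {
            "onsets": onsets[visible],
            "peaks": onsets[visible] + breathing.inspiration_duration,
            "breath_values": values,
            "breath_phase": phases,
            "cardiac_phase": cardiac,
            "drift": drift,
            "heart_rate_bpm": acq.heart_rate_bpm,
            "k_true": breathing.k_true,
        },
    }
    return ProjectionSeries(frames, angles, times, cfg.pixel_size, metadata)


# ---------------------------------------------------------------------------
# ROI suggestions
# ---------------------------------------------------------------------------

def interface_roi(cfg: PhantomConfig, half_height_mm: float = 2.0):
    """Row/col bounds of a rectangle over the lung-diaphragm interface.

    Spans the full body width and ``±half_height_mm`` around the resting
    diaphragm base — the placement with the strongest breathing modulation.
    Returns (row_start, row_end, col_start, col_end), half-open.
    """
    z0 = cfg.z_diaphragm_rest
    r0 = int(max(0, math.floor((z0 - half_height_mm) / cfg.pixel_size)))
    r1 = int(min(cfg.grid_size, math.ceil((z0 + half_height_mm) / cfg.pixel_size)))
    half = cfg.grid_size / 2.0
    c0 = int(max(0, math.floor(half + (cfg.body.cx - cfg.body.a) / cfg.pixel_size)))
    c1 = int(min(cfg.grid_size, math.ceil(half + (cfg.body.cx + cfg.body.a) / cfg.pixel_size)))
    return (r0, r1, c0, c1)


def apex_roi(cfg: PhantomConfig, half_height_mm: float = 2.0):
    """Same-width rectangle over the lung apex (weak breathing modulation)."""
    z0 = cfg.z_apex + cfg.apex_taper_frac * cfg.axial_extent + half_height_mm
    r0 = int(max(0, math.floor((z0 - half_height_mm) / cfg.pixel_size)))
    r1 = int(min(cfg.grid_size, math.ceil((z0 + half_height_mm) / cfg.pixel_size)))
    _, _, c0, c1 = interface_roi(cfg, half_height_mm)
    return (r0, r1, c0, c1)
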