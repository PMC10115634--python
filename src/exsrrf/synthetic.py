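"""Seeded generators for every input class the pipeline consumes.

Widefield acquisition is emulated as a sum of isotropic 2-D Gaussian
point-spread functions over blinking emitters, translated by a drift
trace, with Poisson shot noise and Gaussian read noise.  Blinking is
independent per-frame Bernoulli — the simplest fluctuation model that
provides the temporal radial fluctuations SRRF exploits.  Ridge
lattices and interdigitating foot-process/slit-diaphragm phantoms give
the morphometrics pipeline inputs with known ground truth.

Defaults describe the emulated study conditions: 65 nm camera pixels, a
PSF sigma of 1.3 px (approximately 200 nm FWHM), 50-frame stacks,
blinking on-probability 0.6, and noise yielding a peak signal-to-noise
ratio of 5 at the default emitter brightness of 100 counts.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from exsrrf.stacks_io import Image2D, TimeStack

__all__ = [
    "SyntheticSpec",
    "filament_emitters",
    "make_emitter_stack",
    "make_nanoruler",
    "make_ridge_lattice",
    "make_interdigitation",
]

#: default read-noise sigma: with shot noise, peak SNR = 100/sqrt(100+300) = 5
DEFAULT_READ_SIGMA = math.sqrt(300.0)


@dataclass
class SyntheticSpec:
    """Recipe for a fluctuating-emitter time stack.

    Parameters
    ----------
    image_shape : (Y, X)
        Frame size in pixels.
    emitters : list of (y, x, brightness)
        Subpixel emitter positions and peak brightness in counts.
    psf_sigma_px : float
        Gaussian PSF standard deviation in pixels.
    frames : int
        Number of frames T.
    on_probability : float
        Per-frame Bernoulli probability that an emitter is emitting.
    brightness_sigma : float
        Log-normal frame-to-frame brightness scatter (sigma of log);
        0 disables.
    drift_mode : {"none", "linear", "random_walk", "trace"}
        Lateral drift model.
    drift_rate : (dy, dx)
        Pixels per frame for linear drift; step sigma for random walk.
    drift_trace : (T, 2) array, optional
        Explicit per-frame drift; overrides the model when given.
    shot_noise : bool
        Apply Poisson noise to the signal.
    read_sigma : float
        Gaussian read-noise standard deviation in counts.
    pixel_size_nm : float
        Physical pixel size.
    seed : int
        Seed for all randomness in the generator.
    """

    image_shape: tuple[int, int] = (64, 64)
    emitters: list[tuple[float, float, float]] = field(default_factory=list)
    psf_sigma_px: float = 1.3
    frames: int = 50
    on_probability: float = 1.0
    brightness_sigma: float = 0.0
    drift_mode: str = "none"
    drift_rate: tuple[float, float] = (0.0, 0.0)
    drift_trace: np.ndarray | None = None
    shot_noise: bool = True
    read_sigma: float = DEFAULT_READ_SIGMA
    pixel_size_nm: float = 65.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if not 0 <= self.on_probability <= 1:
            raise ValueError("on_probability must be in [0, 1]")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.drift_mode not in ("none", "linear", "random_walk", "trace"):
            raise ValueError(f"unknown drift_mode {self.drift_mode!r}")
        if self.drift_mode == "trace" and self.drift_trace is None:
            raise ValueError("drift_mode 'trace' needs drift_trace")

    def resolve_drift(self, rng: np.random.Generator) -> np.ndarray:
        """The (T, 2) drift trace implied by the drift model."""
        t = np.arange(self.frames, dtype=float)
        if self.drift_mode == "trace" or self.drift_trace is not None:
            trace = np.asarray(self.drift_trace, dtype=float)
            if trace.shape != (self.frames, 2):
                raise ValueError("drift_trace must have shape (frames, 2)")
            return trace
        if self.drift_mode == "linear":
            return np.outer(t, np.asarray(self.drift_rate, dtype=float))
        if self.drift_mode == "random_walk":
            steps = rng.normal(0.0, self.drift_rate, size=(self.frames, 2))
            steps[0] = 0.0
            return np.cumsum(steps, axis=0)
        return np.zeros((self.frames, 2))

    def validate_geometry(self, drift: np.ndarray) -> None:
        ny, nx = self.image_shape
        for y, x, _ in self.emitters:
            ys = y + drift[:, 0]
            xs = x + drift[:, 1]
            if ys.min() < 0 or ys.max() > ny - 1 or xs.min() < 0 or xs.max() > nx - 1:
                raise ValueError(
                    f"emitter ({y}, {x}) leaves the image under the drift trace"
                )


def filament_emitters(
    seed: int,
    shape: tuple[int, int] = (64, 64),
    n_curves: int = 4,
    margin_px: float = 14.0,
    spacing_px: float = 1.2,
    brightness: float = 100.0,
) -> list[tuple[float, float, float]]:
    """Emitters laid densely along sinusoidal filaments.

    Emulates the curvilinear tissue structures a registration reference
    channel carries: labelling points every ``spacing_px`` along
    ``n_curves`` wavy curves produces a structure-rich frame (unlike
    isolated point emitters, whose frames are mostly empty background).
    ``margin_px`` keeps every emitter inside the frame under drift.
    Brightness scatters by +/-30% uniformly per emitter.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    emitters: list[tuple[float, float, float]] = []
    for _ in range(n_curves):
        y0 = rng.uniform(margin_px, ny - margin_px)
        amp = rng.uniform(3.0, 8.0)
        phase = rng.uniform(0, 2 * math.pi)
        period = rng.uniform(20.0, 40.0)
        x = margin_px
        while x < nx - margin_px:
            y = y0 + amp * math.sin(2 * math.pi * x / period + phase)
            y = min(max(y, margin_px), ny - margin_px)
            emitters.append((float(y), float(x), brightness * rng.uniform(0.7, 1.3)))
            x += spacing_px
    return emitters


def _render_frame(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Sum of separable Gaussian PSFs at subpixel positions."""
    ny, nx = shape
    out = np.zeros(shape, dtype=float)
    yy = np.arange(ny, dtype=float)
    xx = np.arange(nx, dtype=float)
    inv = 1.0 / (2.0 * sigma * sigma)
    for (y, x), a in zip(positions, amplitudes):
        if a == 0:
            continue
        gy = np.exp(-((yy - y) ** 2) * inv)
        gx = np.exp(-((xx - x) ** 2) * inv)
        out += a * np.outer(gy, gx)
    return out


def make_emitter_stack(spec: SyntheticSpec) -> tuple[TimeStack, dict]:
    """Render a blinking-emitter time stack with drift and noise.

    Each frame sums the PSFs of the emitters that are on, shifted by the
    frame's drift, then Poisson shot noise and Gaussian read noise are
    applied.

    Returns
    -------
    (TimeStack, dict)
        The stack (single channel) and ground truth with keys
        ``drift`` (T, 2), ``positions`` (N, 2), ``brightness`` (N,),
        ``on`` (T, N) and ``frame_brightness`` (T, N).
    """
    if not spec.emitters:
        raise ValueError("spec has no emitters")
    rng = np.random.default_rng(spec.seed)
    drift = spec.resolve_drift(rng)
    spec.validate_geometry(drift)

    positions = np.array([(e[0], e[1]) for e in spec.emitters], dtype=float)
    brightness = np.array([e[2] for e in spec.emitters], dtype=float)
    nt, n = spec.frames, positions.shape[0]

    on = rng.random((nt, n)) < spec.on_probability
    scale = (
        rng.lognormal(0.0, spec.brightness_sigma, size=(nt, n))
        if spec.brightness_sigma > 0
        else np.ones((nt, n))
    )
    frame_brightness = on * scale * brightness[None, :]

    frames = np.empty((nt, 1) + tuple(spec.image_shape), dtype=float)
    for t in range(nt):
        signal = _render_frame(
            spec.image_shape, positions + drift[t], frame_brightness[t], spec.psf_sigma_px
        )
        if spec.shot_noise:
            signal = rng.poisson(signal).astype(float)
        if spec.read_sigma > 0:
            signal = signal + rng.normal(0.0, spec.read_sigma, size=signal.shape)
        frames[t, 0] = signal

    stack = TimeStack(frames, pixel_size_nm=spec.pixel_size_nm)
    truth = {
        "drift": drift,
        "positions": positions,
        "brightness": brightness,
        "on": on,
        "frame_brightness": frame_brightness,
    }
    return stack, truth


def make_nanoruler(
    distance_nm: float,
    expansion_factor: float = 1.0,
    image_shape: tuple[int, int] = (32, 32),
    orientation_deg: float = 0.0,
    brightness: float = 400.0,
    on_probability: float = 0.6,
    frames: int = 50,
    psf_sigma_px: float = 1.3,
    pixel_size_nm: float = 65.0,
    shot_noise: bool = True,
    read_sigma: float = DEFAULT_READ_SIGMA,
    seed: int = 0,
) -> tuple[TimeStack, dict]:
    """Two blinking emitters at a fabricated physical distance.

    The centre separation in pixels is
    ``distance_nm * expansion_factor / pixel_size_nm``; expansion
    multiplies the physical separation before projection onto the
    camera.  Raises when the projected separation falls below 0.1 px.

    The default mark brightness (400 counts, peak SNR ~ 16 with the
    default read noise) reflects that a nanoruler mark carries tens of
    fluorophores and is imaged at optimized exposure, unlike the
    single-emitter default of :class:`SyntheticSpec`.
    """
    if distance_nm <= 0:
        raise ValueError("distance_nm must be > 0")
    if expansion_factor < 1:
        raise ValueError("expansion_factor must be >= 1")
    separation_px = distance_nm * expansion_factor / pixel_size_nm
    if separation_px < 0.1:
        raise ValueError(f"projected separation {separation_px:.3f} px is below 0.1 px")
    cy = (image_shape[0] - 1) / 2.0
    cx = (image_shape[1] - 1) / 2.0
    ang = math.radians(orientation_deg)
    dy = 0.5 * separation_px * math.sin(ang)
    dx = 0.5 * separation_px * math.cos(ang)
    emitters = [
        (cy - dy, cx - dx, brightness),
        (cy + dy, cx + dx, brightness),
    ]
    spec = SyntheticSpec(
        image_shape=image_shape,
        emitters=emitters,
        psf_sigma_px=psf_sigma_px,
        frames=frames,
        on_probability=on_probability,
        shot_noise=shot_noise,
        read_sigma=read_sigma,
        pixel_size_nm=pixel_size_nm,
        seed=seed,
    )
    stack, truth = make_emitter_stack(spec)
    truth["separation_px"] = separation_px
    truth["separation_nm"] = distance_nm * expansion_factor
    return stack, truth


def make_ridge_lattice(
    period_px: float,
    line_width_px: float,
    orientation_deg: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    phase_px: float = 0.5,
) -> tuple[Image2D, dict]:
    """Anti-aliased parallel bright lines with known density and spacing.

    Lines run along ``orientation_deg`` (degrees from the x axis) with
    centre-to-centre ``period_px`` and width ``line_width_px``.  Ground
    truth: ``density = line_width / period`` and inter-ridge gap
    ``period - line_width``.  ``phase_px`` offsets the midlines across
    the lines; the half-pixel default keeps axis-aligned midlines off
    exact pixel centres (the degenerate symmetry would quantize mask
    widths to odd pixel counts).
    """
    if not period_px > line_width_px >= 1:
        raise ValueError("need period_px > line_width_px >= 1")
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    ang = math.radians(orientation_deg)
    # signed distance across the line direction
    s = yy * math.cos(ang) - xx * math.sin(ang)
    phase = np.mod(s - phase_px, period_px)
    dist = np.minimum(phase, period_px - phase)
    intensity = np.clip(line_width_px / 2.0 + 0.5 - dist, 0.0, 1.0)
    truth = {
        "density": line_width_px / period_px,
        "gap_px": period_px - line_width_px,
        "period_px": period_px,
        "line_width_px": line_width_px,
        "orientation_deg": orientation_deg,
    }
    return Image2D(intensity), truth


def _segment_distance(
    yy: np.ndarray, xx: np.ndarray, p0: tuple[float, float], p1: tuple[float, float]
) -> np.ndarray:
    """Distance from every pixel to the segment p0-p1."""
    py, px = p0
    qy, qx = p1
    vy, vx = qy - py, qx - px
    vv = vy * vy + vx * vx
    if vv == 0:
        return np.hypot(yy - py, xx - px)
    t = np.clip(((yy - py) * vy + (xx - px) * vx) / vv, 0.0, 1.0)
    return np.hypot(yy - (py + t * vy), xx - (px + t * vx))


def make_interdigitation(
    fp_width_px: float = 12.0,
    sd_gap_px: float = 4.0,
    waviness: float = 0.0,
    shape: tuple[int, int] = (384, 384),
    deletion_fraction: float = 0.0,
    margin_px: int = 36,
    seed: int = 0,
) -> tuple[Image2D, Image2D, dict]:
    """Interdigitating foot-process phantom with a slit-diaphragm meander.

    A square-wave meander curve of thickness ``sd_gap_px`` runs across
    the frame, alternating between an upper and a lower level every
    ``fp_width_px + sd_gap_px`` pixels; the regions interlocking on
    either side are the foot processes, ``fp_width_px`` wide.
    ``waviness`` (px) perturbs the levels sinusoidally with a seeded
    phase.  The "effaced" variant deletes ``deletion_fraction`` of the
    meander segments (seeded choice) — deleted transitions merge
    adjacent processes, emulating slit-diaphragm loss; pass a widened
    ``fp_width_px`` to emulate process broadening.  Deletion fraction 1
    leaves an empty separator channel.

    Returns
    -------
    (fp_image, sd_image, truth)
        FP channel (processes bright, separator dark), SD channel (the
        meander curve bright), and ground truth with the curve segments,
        finger count and deleted-transition indices.
    """
    if fp_width_px < 1 or sd_gap_px < 1:
        raise ValueError("fp_width_px and sd_gap_px must be >= 1 px")
    if not 0 <= deletion_fraction <= 1:
        raise ValueError("deletion_fraction must be in [0, 1]")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    period = fp_width_px + sd_gap_px
    y_lo = float(margin_px)
    y_hi = float(ny - margin_px)
    n_seg = int(nx // period)
    if n_seg < 2 or y_hi - y_lo < 2 * period:
        raise ValueError("shape too small for the requested geometry")

    phase = rng.uniform(0, 2 * math.pi)
    wavelength = 4.0 * period

    def level(i: int, x: float) -> float:
        base = y_lo if i % 2 == 0 else y_hi
        return base + waviness * math.sin(2 * math.pi * x / wavelength + phase)

    horizontals: list[tuple[tuple[float, float], tuple[float, float], int]] = []
    verticals: list[tuple[tuple[float, float], tuple[float, float], int]] = []
    for i in range(n_seg):
        x0 = i * period
        x1 = min((i + 1) * period, float(nx - 1))
        horizontals.append(((level(i, x0), x0), (level(i, x1), x1), i))
        if i + 1 < n_seg:
            verticals.append(((level(i, x1), x1), (level(i + 1, x1), x1), i))

    all_segments = [h[:2] for h in horizontals] + [v[:2] for v in verticals]
    n_delete = int(round(deletion_fraction * len(all_segments)))
    deleted = (
        set(rng.choice(len(all_segments), size=n_delete, replace=False).tolist())
        if n_delete
        else set()
    )

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    dist = np.full(shape, np.inf)
    kept_segments = [s for j, s in enumerate(all_segments) if j not in deleted]
    for p0, p1 in kept_segments:
        np.minimum(dist, _segment_distance(yy, xx, p0, p1), out=dist)

    half = sd_gap_px / 2.0
    if kept_segments:
        sd = np.clip(half + 0.5 - dist, 0.0, 1.0)
        fp = np.clip(dist - half + 0.5, 0.0, 1.0)
    else:
        sd = np.zeros(shape)
        fp = np.ones(shape)

    truth = {
        "fp_width_px": fp_width_px,
        "sd_gap_px": sd_gap_px,
        "n_fingers": n_seg,
        "n_segments": len(all_segments),
        "deleted_segments": sorted(deleted),
        "segments": kept_segments,
        "y_levels": (y_lo, y_hi),
    }
    return Image2D(fp), Image2D(sd), truth
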