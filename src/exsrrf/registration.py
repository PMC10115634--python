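"""Frame-to-first drift registration of fluorescence time stacks.

Every frame is aligned to the first frame of the stack using one
reference channel.  The reference frames are smoothed with a Gaussian
(sigma 1 px), the lower 90th percentile of pixel values is zeroed so
only the brightest structures drive the alignment, and each moving
frame's histogram is matched to the reference histogram.  The residual
translation is then estimated by cross-correlation maximized with
discrete-Fourier-transform upsampling (default 1/100 px precision) and
removed from all channels, cropping and padding to the original size.

Sign convention: :func:`estimate_shift` returns the drift ``(dy, dx)``
of the moving frame relative to the reference, i.e. the translation
that maps reference coordinates onto moving coordinates.  Applying
``-(dy, dx)`` to the moving frame aligns it to the reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms
from skimage.registration import phase_cross_correlation

from exsrrf.stacks_io import Image2D, TimeStack

__all__ = [
    "RegistrationConfig",
    "DriftTrace",
    "ShiftEstimationError",
    "preprocess_reference",
    "match_histogram",
    "estimate_shift",
    "register_stack",
    "apply_shift",
]

logger = logging.getLogger(__name__)


class ShiftEstimationError(RuntimeError):
    """Raised when the shift between two frames cannot be estimated."""


@dataclass
class RegistrationConfig:
    """Settings for frame-to-first registration.

    Parameters
    ----------
    reference_channel : int
        Channel containing the main structure of interest; drives the
        shift estimate for all channels.
    smooth_sigma : float
        Gaussian standard deviation (pixels) for reference smoothing.
    keep_percentile : float
        Percentile below which smoothed pixel values are zeroed; the
        default keeps only the upper 10% of pixel values.
    upsample_factor : int
        Subpixel precision of the DFT shift estimate (100 = 1/100 px).
    fill_value : float
        Intensity written into regions exposed by the shift.
    subpixel : bool
        Apply the fractional part of the shift by first-order
        interpolation (default); if False, shifts are rounded to whole
        pixels before application.
    """

    reference_channel: int = 0
    smooth_sigma: float = 1.0
    keep_percentile: float = 90.0
    upsample_factor: int = 100
    fill_value: float = 0.0
    subpixel: bool = True

    def __post_init__(self) -> None:
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be > 0")
        if not 0 <= self.keep_percentile < 100:
            raise ValueError("keep_percentile must be in [0, 100)")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")


@dataclass
class DriftTrace:
    """Per-frame drift estimates and the masks valid after correction.

    ``shifts[t]`` is the estimated drift ``(dy, dx)`` of frame ``t``
    relative to frame 0 (frame 0 is fixed at ``(0, 0)``);
    ``overlap_masks[t]`` flags the pixels of the corrected frame that
    originate from measured data rather than padding.
    """

    shifts: np.ndarray
    overlap_masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be an (T, 2) array of (dy, dx)")
        if not np.allclose(self.shifts[0], 0.0):
            raise ValueError("frame 0 must have zero shift")

    def __len__(self) -> int:
        return self.shifts.shape[0]

    def offsets(self) -> np.ndarray:
        """Per-frame 2-norm of the (dy, dx) shift, in pixels."""
        return np.hypot(self.shifts[:, 0], self.shifts[:, 1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"frame": np.arange(len(self)), "dy_px": self.shifts[:, 0], "dx_px": self.shifts[:, 1]}
        )

    @classmethod
    def from_csv(cls, path) -> "DriftTrace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(np.column_stack([df["dy_px"], df["dx_px"]]))


def preprocess_reference(frame: Image2D, config: RegistrationConfig | None = None) -> Image2D:
    """Smooth a reference frame and zero everything below the keep percentile.

    The frame is convolved with a Gaussian of ``config.smooth_sigma`` and
    all pixels at or below the ``keep_percentile`` value of the smoothed
    frame are set to 0, so only the brightest structures remain.  A
    constant frame maps to all zeros.
    """
    config = config or RegistrationConfig()
    data = np.asarray(frame.data, dtype=float)
    smoothed = ndimage.gaussian_filter(data, sigma=config.smooth_sigma)
    cutoff = np.percentile(smoothed, config.keep_percentile)
    out = np.where(smoothed > cutoff, smoothed, 0.0)
    return Image2D(out, pixel_size_nm=frame.pixel_size_nm)


def match_histogram(moving: Image2D, reference: Image2D) -> Image2D:
    """Remap ``moving`` so its intensity distribution matches ``reference``.

    A monotone rank-preserving remap: the sorted values of the output
    equal the sorted values of the reference (up to ties).
    """
    out = match_histograms(np.asarray(moving.data, dtype=float), np.asarray(reference.data, dtype=float))
    return Image2D(out, pixel_size_nm=moving.pixel_size_nm)


def estimate_shift(
    reference: Image2D, moving: Image2D, upsample_factor: int = 100
) -> tuple[float, float]:
    """Estimate the subpixel drift ``(dy, dx)`` of ``moving`` vs ``reference``.

    Cross-correlation is maximized with DFT upsampling at
    ``1/upsample_factor`` px precision.  The returned shift is the
    translation of the moving frame relative to the reference; applying
    its negation to the moving frame aligns the pair.

    Raises
    ------
    ShiftEstimationError
        If either input is entirely zero.
    """
    ref = np.asarray(reference.data, dtype=float)
    mov = np.asarray(moving.data, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if not ref.any():
        raise ShiftEstimationError("reference frame is all zero; cannot estimate shift")
    if not mov.any():
        raise ShiftEstimationError("moving frame is all zero; cannot estimate shift")
    correction, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample_factor, normalization=None
    )
    # phase_cross_correlation returns the shift that registers moving onto
    # reference; the drift is its negation.
    return float(-correction[0]), float(-correction[1])


def apply_shift(
    frame: np.ndarray, shift: tuple[float, float], fill_value: float = 0.0, subpixel: bool = True
) -> np.ndarray:
    """Translate a 2-D frame by ``shift`` (dy, dx), crop-and-pad to size.

    The integer part is applied by cropping and padding with
    ``fill_value``; the fractional part (when ``subpixel``) by
    first-order interpolation.
    """
    dy, dx = float(shift[0]), float(shift[1])
    if not subpixel:
        dy, dx = round(dy), round(dx)
    order = 1 if subpixel else 0
    out = ndimage.shift(
        np.asarray(frame, dtype=float), (dy, dx), order=order, mode="constant", cval=fill_value
    )
    return out


def overlap_mask(shape: tuple[int, int], shift: tuple[float, float]) -> np.ndarray:
    """Boolean mask of pixels valid after correcting a drift of ``shift``.

    The corrected frame ``out[y, x] = in[y + dy, x + dx]`` is valid where
    the source coordinate falls inside the frame; fractional shifts are
    treated conservatively (both touched pixels must exist).
    """
    ny, nx = shape
    dy, dx = float(shift[0]), float(shift[1])
    y0 = max(0, math.ceil(-dy))
    y1 = min(ny, ny - math.ceil(dy))
    x0 = max(0, math.ceil(-dx))
    x1 = min(nx, nx - math.ceil(dx))
    mask = np.zeros(shape, dtype=bool)
    if y1 > y0 and x1 > x0:
        mask[y0:y1, x0:x1] = True
    return mask


def register_stack(
    stack: TimeStack, config: RegistrationConfig | None = None
) -> tuple[TimeStack, DriftTrace]:
    """Align every frame of a time stack to its first frame.

    The drift of each reference-channel frame against frame 0 is
    estimated after preprocessing (smooth, percentile-zero, histogram
    match, in that order) and removed from **all** channels, which are
    cropped and padded with ``config.fill_value`` to retain the original
    size.  Frame 0 passes through unchanged.

    Returns
    -------
    (TimeStack, DriftTrace)
        The registered stack and the per-frame drift trace with overlap
        masks.

    Raises
    ------
    ShiftEstimationError
        Naming the frame index, if the shift of a frame cannot be
        estimated even from raw intensities.
    """
    config = config or RegistrationConfig()
    if stack.frame_count < 2:
        raise ValueError("register_stack needs a stack with at least 2 frames")
    if not 0 <= config.reference_channel < stack.n_channels:
        raise IndexError(
            f"reference_channel {config.reference_channel} out of range "
            f"for {stack.n_channels}-channel stack"
        )

    nt = stack.frame_count
    ref_raw = stack.frame(0, config.reference_channel)
    ref_pre = preprocess_reference(ref_raw, config)
    shifts = np.zeros((nt, 2), dtype=float)

    for t in range(1, nt):
        mov_raw = stack.frame(t, config.reference_channel)
        mov_pre = preprocess_reference(mov_raw, config)
        try:
            if not ref_pre.data.any() or not mov_pre.data.any():
                # degenerate after preprocessing: fall back to raw intensities
                logger.warning(
                    "frame %d: preprocessed reference is empty, falling back to raw correlation", t
                )
                shifts[t] = estimate_shift(ref_raw, mov_raw, config.upsample_factor)
            else:
                mov_matched = match_histogram(mov_pre, ref_pre)
                shifts[t] = estimate_shift(ref_pre, mov_matched, config.upsample_factor)
        except ShiftEstimationError as exc:
            raise ShiftEstimationError(f"frame {t}: {exc}") from exc

    registered = np.empty_like(stack.data, dtype=float)
    registered[0] = stack.data[0]
    masks = [np.ones(stack.frame_shape, dtype=bool)]
    for t in range(1, nt):
        for c in range(stack.n_channels):
            # undo the drift: translate by the negated estimated shift
            registered[t, c] = apply_shift(
                stack.data[t, c],
                (-shifts[t, 0], -shifts[t, 1]),
                fill_value=config.fill_value,
                subpixel=config.subpixel,
            )
        masks.append(overlap_mask(stack.frame_shape, shifts[t]))

    out = TimeStack(
        registered, pixel_size_nm=stack.pixel_size_nm, channel_names=list(stack.channel_names)
    )
    return out, DriftTrace(shifts, overlap_masks=masks)
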