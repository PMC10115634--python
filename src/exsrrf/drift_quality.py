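"""Quantifying drift and the benefit of registration.

For every frame the drift magnitude is the 2-norm of its ``(dy, dx)``
offset, summarized per stack as the *mean offset* and the *last offset*
(the final frame usually drifts furthest).  Image similarity against
frame 0 — mean structural similarity (MSSIM) and mean squared error
(MSE) — is computed before and after registration, restricted to the
overlap region so the two are comparable.  Registration deltas are
``before - after``: a negative MSSIM delta and a positive MSE delta
both indicate improvement.  Cohorts of stacks are stratified into low
vs high drift at ``mean + 0.5 x s.d.`` of the per-stack offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from exsrrf.registration import DriftTrace
from exsrrf.stacks_io import Image2D, TimeStack

__all__ = [
    "DriftMetrics",
    "offset_summary",
    "similarity_metrics",
    "stratify_drift",
    "ridge_ssim",
]

logger = logging.getLogger(__name__)

#: structural-similarity window: 7x7, Gaussian-weighted (sigma 1.5)
SSIM_WIN_SIZE = 7
SSIM_SIGMA = 1.5


@dataclass
class DriftMetrics:
    """Per-stack drift magnitudes and registration-quality deltas.

    ``per_frame_offset`` holds the 2-norm of each frame's drift in
    pixels.  The similarity arrays are per-frame values against frame 0
    on the overlap region; NaN marks frames whose overlap was empty.
    Deltas are ``before - after``; ``delta_mssim < 0`` and
    ``delta_mse > 0`` signal improvement through registration.
    """

    per_frame_offset: np.ndarray
    mean_offset: float
    last_offset: float
    mssim_before: np.ndarray = field(default_factory=lambda: np.empty(0))
    mssim_after: np.ndarray = field(default_factory=lambda: np.empty(0))
    mse_before: np.ndarray = field(default_factory=lambda: np.empty(0))
    mse_after: np.ndarray = field(default_factory=lambda: np.empty(0))

    def _mean(self, arr: np.ndarray) -> float:
        valid = arr[~np.isnan(arr)]
        return float(valid.mean()) if valid.size else float("nan")

    @property
    def delta_mssim(self) -> float:
        """Mean over frames of (MSSIM before - MSSIM after)."""
        return self._mean(self.mssim_before - self.mssim_after)

    @property
    def delta_mse(self) -> float:
        """Mean over frames of (MSE before - MSE after)."""
        return self._mean(self.mse_before - self.mse_after)

    @property
    def delta_mssim_last(self) -> float:
        return float(self.mssim_before[-1] - self.mssim_after[-1])

    @property
    def delta_mse_last(self) -> float:
        return float(self.mse_before[-1] - self.mse_after[-1])

    def to_dict(self) -> dict:
        return {
            "mean_offset_px": self.mean_offset,
            "last_offset_px": self.last_offset,
            "mssim_before_mean": self._mean(self.mssim_before),
            "mssim_after_mean": self._mean(self.mssim_after),
            "mse_before_mean": self._mean(self.mse_before),
            "mse_after_mean": self._mean(self.mse_after),
            "delta_mssim": self.delta_mssim,
            "delta_mse": self.delta_mse,
        }


def offset_summary(trace: DriftTrace) -> tuple[float, float]:
    """Mean offset (over frames 1..T-1) and last-frame offset, in pixels.

    A single-frame trace has no moving frames; both summaries are 0.
    """
    offsets = trace.offsets()
    if len(trace) < 2:
        return 0.0, 0.0
    return float(offsets[1:].mean()), float(offsets[-1])


def _rescale01(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi > lo:
        return (img - lo) / (hi - lo)
    return np.zeros_like(img)


def _frame_similarity(ref: np.ndarray, frame: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """(MSSIM, MSE) between two frames on the bounding box of ``mask``.

    Both metrics are computed on raw intensities so before/after values
    share one scale; the SSIM stabilizing constants use the joint
    intensity range of the pair.
    """
    if not mask.any():
        return float("nan"), float("nan")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    ref_c = ref[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].astype(float)
    frm_c = frame[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].astype(float)
    if min(ref_c.shape) < SSIM_WIN_SIZE:
        return float("nan"), float("nan")
    data_range = max(ref_c.max(), frm_c.max()) - min(ref_c.min(), frm_c.min())
    if data_range == 0:
        return 1.0, 0.0
    mssim = structural_similarity(
        ref_c,
        frm_c,
        win_size=SSIM_WIN_SIZE,
        gaussian_weights=True,
        sigma=SSIM_SIGMA,
        data_range=data_range,
    )
    mse = float(np.mean((ref_c - frm_c) ** 2))
    return float(mssim), mse


def similarity_metrics(
    stack_before: TimeStack,
    stack_after: TimeStack,
    trace: DriftTrace,
    channel: int = 0,
) -> DriftMetrics:
    """MSSIM/MSE against frame 0, before vs after registration.

    Both stacks are compared frame-by-frame with their own frame 0 on
    the overlap region recorded in ``trace`` (the region that remains
    measured data after correcting the drift), so padded borders never
    enter the metrics.  Frames with an empty overlap are flagged NaN and
    excluded from the mean summaries with a logged warning.
    """
    if stack_before.data.shape != stack_after.data.shape:
        raise ValueError("before/after stacks must share a shape")
    nt = stack_before.frame_count
    if len(trace) != nt:
        raise ValueError("trace length must equal the frame count")

    offsets = trace.offsets()
    mean_off, last_off = offset_summary(trace)
    mssim_b = np.empty(nt)
    mssim_a = np.empty(nt)
    mse_b = np.empty(nt)
    mse_a = np.empty(nt)
    ref_b = stack_before.data[0, channel]
    ref_a = stack_after.data[0, channel]
    for t in range(nt):
        mask = (
            trace.overlap_masks[t]
            if trace.overlap_masks
            else np.ones(stack_before.frame_shape, dtype=bool)
        )
        if not mask.any():
            logger.warning("frame %d: empty overlap; similarity flagged missing", t)
        mssim_b[t], mse_b[t] = _frame_similarity(ref_b, stack_before.data[t, channel], mask)
        mssim_a[t], mse_a[t] = _frame_similarity(ref_a, stack_after.data[t, channel], mask)

    return DriftMetrics(
        per_frame_offset=offsets,
        mean_offset=mean_off,
        last_offset=last_off,
        mssim_before=mssim_b,
        mssim_after=mssim_a,
        mse_before=mse_b,
        mse_after=mse_a,
    )


def stratify_drift(
    metrics: list[DriftMetrics], absolute_threshold: bool = False
) -> tuple[list[str], float]:
    """Split a cohort of stacks into low- vs high-drift groups.

    The per-stack statistic is the mean offset.  The default threshold
    is ``mean + 0.5 x s.d.`` of those statistics across the cohort
    ("0.5 s.d. from the mean"); with ``absolute_threshold`` the cut is
    at ``0.5 x s.d.`` alone.

    Returns
    -------
    (labels, threshold)
        One ``"low drift"`` / ``"high drift"`` label per stack, and the
        threshold applied.
    """
    if len(metrics) < 2:
        raise ValueError("stratify_drift needs at least 2 stacks")
    values = np.array([m.mean_offset for m in metrics], dtype=float)
    sd = float(values.std())
    threshold = 0.5 * sd if absolute_threshold else float(values.mean()) + 0.5 * sd
    labels = ["high drift" if v > threshold else "low drift" for v in values]
    return labels, threshold


def ridge_ssim(image: Image2D, ridges: Image2D) -> float:
    """Structural similarity between an image and its ridge response.

    Both inputs are rescaled to [0, 1] before comparison; values closer
    to 1 mean the detected ridges track the underlying structures
    better, i.e. the image is sharp enough for reliable segmentation.
    Constant inputs are handled by the SSIM stabilizing constants and
    compare as identical (similarity 1 for two flat images).
    """
    a = np.asarray(image.data, dtype=float)
    b = np.asarray(ridges.data, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image and ridge response must share a shape")
    a = _rescale01(a, a.min(), a.max())
    b = _rescale01(b, b.min(), b.max())
    return float(
        structural_similarity(
            a, b, win_size=SSIM_WIN_SIZE, gaussian_weights=True, sigma=SSIM_SIGMA, data_range=1.0
        )
    )
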