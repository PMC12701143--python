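"""Scar-detection thresholds: FWHM and n-standard-deviations (nSD).

FWHM takes the brightest pixel intensity inside the ROI (``b_roi``) and
walks halfway back toward the darkest pixel of the myocardium
(``d_myo``)::

    t_fwhm = b_roi - (b_roi - d_myo) / 2

The nSD threshold assumes the remote (healthy) myocardium is normally
distributed and sets::

    t_nsd = m_remote + n * sd_remote

where mean and SD are computed from the fractionally weighted pixel
sample of the remote region.  The SD uses reliability weights with the
standard unbiased correction

    s^2 = sum(w_i (x_i - m)^2) * W / (W^2 - sum(w_i^2)),   W = sum(w_i)

which reduces exactly to the textbook unbiased sample SD when all
weights are equal.

Extremes (max over ROI, min over myocardium) are taken over the full
support of the exact mask: a pixel only partially inside the contour
still counts, matching how the weighted histograms are displayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateReferenceError,
    MissingGroundworkError,
    MissingReferenceError,
    UsageError,
)
from .raster import WeightedSample

__all__ = [
    "ThresholdResult",
    "weighted_mean",
    "weighted_sd",
    "fwhm_threshold",
    "nsd_threshold",
    "NSD_MIN_N",
    "NSD_MAX_N",
]

NSD_MIN_N = 1
NSD_MAX_N = 9


@dataclass(frozen=True)
class ThresholdResult:
    """A per-slice threshold with the quantities that produced it."""

    sop_uid: str
    method: str  # "fwhm" or "nsd"
    threshold: float
    inputs_summary: dict

    def __post_init__(self) -> None:
        if self.method not in ("fwhm", "nsd"):
            raise UsageError(f"unknown threshold method {self.method!r}")


def weighted_mean(sample: WeightedSample) -> float:
    """Weighted mean  sum(x w) / sum(w)."""
    if sample.is_empty:
        raise UsageError("weighted_mean of an empty sample")
    return float(np.sum(sample.values * sample.weights) / np.sum(sample.weights))


def weighted_sd(sample: WeightedSample) -> float:
    """Bias-corrected reliability-weighted standard deviation."""
    if sample.is_empty:
        raise UsageError("weighted_sd of an empty sample")
    w = sample.weights
    W = float(np.sum(w))
    W2 = float(np.sum(w * w))
    if len(sample) < 2 or W * W <= W2:
        raise DegenerateReferenceError(
            "reference sample has effective size <= 1; cannot estimate SD"
        )
    m = weighted_mean(sample)
    var = float(np.sum(w * (sample.values - m) ** 2)) * W / (W * W - W2)
    # clamp tiny negative rounding noise for constant samples
    return float(np.sqrt(max(var, 0.0)))


def fwhm_threshold(
    myo_sample: WeightedSample, roi_sample: WeightedSample, sop_uid: str = ""
) -> ThresholdResult:
    """Full-width-at-half-maximum threshold from myocardium + ROI samples."""
    if roi_sample.is_empty:
        raise MissingReferenceError("FWHM requires a non-empty ROI sample")
    if myo_sample.is_empty:
        raise MissingGroundworkError("FWHM requires a non-empty myocardial sample")
    b_roi = float(np.max(roi_sample.values))
    d_myo = float(np.min(myo_sample.values))
    t = b_roi - 0.5 * (b_roi - d_myo)
    return ThresholdResult(
        sop_uid=sop_uid,
        method="fwhm",
        threshold=t,
        inputs_summary={"b_roi": b_roi, "d_myo": d_myo},
    )


def nsd_threshold(
    remote_sample: WeightedSample, n: int, sop_uid: str = ""
) -> ThresholdResult:
    """Threshold at n standard deviations above the remote mean."""
    if not isinstance(n, (int, np.integer)) or not NSD_MIN_N <= n <= NSD_MAX_N:
        raise UsageError(
            f"n must be an integer in [{NSD_MIN_N}, {NSD_MAX_N}], got {n!r}"
        )
    if remote_sample.is_empty:
        raise MissingReferenceError("nSD requires a non-empty remote sample")
    m = weighted_mean(remote_sample)
    s = weighted_sd(remote_sample)
    return ThresholdResult(
        sop_uid=sop_uid,
        method="nsd",
        threshold=m + n * s,
        inputs_summary={"m_remote": m, "sd_remote": s, "n": int(n)},
    )
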