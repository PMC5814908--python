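"""Image-quality metrics: ghosting level, SNR, SSIM and phase-encode
bandwidth arithmetic.

The ghosting level quantifies the excess mean magnitude in the half-FOV
shifted copies of the object region:

    ghosting = (mean r1 + mean r2 - mean r3 - mean r4) / (2 * mean r5) * 100

where region 5 is the object, regions 1/2 are the object mask circularly
shifted by N/2 along the phase-encode direction (split at the image midline
into its two pieces — where the Nyquist ghost lands) and regions 3/4 are the
same shift along the frequency-encode direction (pure background under the
odd/even phase-error model, so they subtract the noise floor).  Negative
values can occur from noise fluctuation and are not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["RoiSet", "ghosting_level", "snr", "ssim", "pe_pixel_bandwidth"]


@dataclass
class RoiSet:
    """Object region plus the four shifted measurement regions.

    Regions may be user-supplied (restricted-FOV / multi-source case, where
    all five areas are drawn manually); :meth:`from_object_mask` builds the
    standard construction.
    """

    region1: np.ndarray
    region2: np.ndarray
    region3: np.ndarray
    region4: np.ndarray
    region5: np.ndarray

    def __post_init__(self):
        masks = [np.asarray(getattr(self, "region%d" % i), dtype=bool)
                 for i in range(1, 6)]
        shapes = {m.shape for m in masks}
        if len(shapes) > 1:
            raise ValueError("all regions must share one grid shape")
        if not masks[4].any():
            raise ValueError("object region (region5) must be non-empty")
        for i, m in enumerate(masks):
            setattr(self, "region%d" % (i + 1), m)

    @classmethod
    def from_object_mask(cls, mask: np.ndarray) -> "RoiSet":
        """Standard construction: regions 1/2 = PE-direction N/2 shift of
        the object split at the PE midline; regions 3/4 = readout-direction
        shift split at the readout midline."""
        mask = np.asarray(mask, dtype=bool)
        n_ro, n_pe = mask.shape
        pe_shift = np.roll(mask, n_pe // 2, axis=1)
        ro_shift = np.roll(mask, n_ro // 2, axis=0)
        col = np.arange(n_pe)[None, :]
        row = np.arange(n_ro)[:, None]
        return cls(
            region1=pe_shift & (col < n_pe // 2),
            region2=pe_shift & (col >= n_pe // 2),
            region3=ro_shift & (row < n_ro // 2),
            region4=ro_shift & (row >= n_ro // 2),
            region5=mask,
        )

    @property
    def noise_mask(self) -> np.ndarray:
        """Readout-shifted background (regions 3 and 4) — ghost-free under
        the odd/even phase-error model, usable as a noise region."""
        return self.region3 | self.region4


def _region_mean(mag: np.ndarray, mask: np.ndarray, name: str) -> float:
    if not mask.any():
        raise ValueError("%s is empty" % name)
    return float(mag[mask].mean())


def ghosting_level(img_magnitude: np.ndarray, rois: RoiSet) -> float:
    """Ghosting level in percent (see module docstring); magnitude input."""
    mag = np.asarray(img_magnitude, dtype=float)
    if not np.all(np.isfinite(mag)):
        raise ValueError("magnitudes must be finite")
    m = [_region_mean(mag, getattr(rois, "region%d" % i), "region%d" % i)
         for i in range(1, 6)]
    if m[4] == 0:
        raise ValueError("object region mean is zero; ghosting level undefined")
    return (m[0] + m[1] - m[2] - m[3]) / (2.0 * m[4]) * 100.0


def snr(img_magnitude: np.ndarray, object_mask: np.ndarray,
        noise_mask: np.ndarray,
        noise_image: Optional[np.ndarray] = None) -> float:
    """Mean object magnitude over the SD of magnitude in a noise region.

    The noise region may live in the same image or in a designated
    noise-only frame (``noise_image``), e.g. the last pyruvate frame of a
    dynamic series.
    """
    mag = np.asarray(img_magnitude, dtype=float)
    obj = np.asarray(object_mask, dtype=bool)
    nz = np.asarray(noise_mask, dtype=bool)
    if not obj.any() or not nz.any():
        raise ValueError("object and noise masks must be non-empty")
    noise_mag = mag if noise_image is None else np.asarray(noise_image, dtype=float)
    sd = float(noise_mag[nz].std())
    if sd == 0:
        raise ValueError("noise standard deviation is zero; SNR undefined")
    return float(mag[obj].mean()) / sd


def ssim(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Mean local structural similarity (7x7 Gaussian window, sigma 1.5,
    K1=0.01, K2=0.03, dynamic range = joint maximum)."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    data_range = max(float(a.max()), float(b.max())) - min(
        float(a.min()), float(b.min()), 0.0
    )
    if data_range == 0:
        return 1.0
    return float(
        structural_similarity(
            a, b,
            win_size=7, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
            data_range=data_range,
        )
    )


def pe_pixel_bandwidth(n_pe: int, echo_spacing: float) -> float:
    """Per-pixel bandwidth along phase-encode: 1 / (n_pe * echo_spacing), Hz.

    This is the B0 offset that shifts the image by one pixel in the
    phase-encode direction — e.g. 32 lines at 552 us echo spacing give
    ~57 Hz of off-resonance immunity per pixel.
    """
    if n_pe < 1 or echo_spacing <= 0:
        raise ValueError("n_pe must be >= 1 and echo_spacing positive")
    return 1.0 / (n_pe * echo_spacing)
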