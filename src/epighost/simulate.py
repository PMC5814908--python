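"""Synthetic EPI acquisitions: phantoms, corrupted k-space, reference scans,
integrated reference echoes and dynamic two-metabolite series.

The generator emulates the study conditions of single-shot 13C EPI of
hyperpolarized [1-13C]pyruvate/lactate: a 32x32 matrix read with a train of
20 bipolar readout echoes (4 k-space lines before the centre, 62.5% partial
Fourier, zero-filled), an alternating odd/even phase error theta(x) =
alpha + beta*x, optional per-echo T2* decay, complex Gaussian noise on the
acquired lines, and a dynamic series acquired alternately for two metabolites
at a TR of 2 s per metabolite.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterator, List, Optional, Tuple

import numpy as np

from .model import (
    GAMMA_RATIO_C13_H1,
    EpiKspace,
    ImageGrid,
    PhaseCoeffs,
    apply_phase_error,
    image_to_kspace,
    kspace_to_hybrid,
    hybrid_to_kspace,
    reconstruct,
)

__all__ = [
    "EllipseShape",
    "PhantomSpec",
    "AcquisitionParams",
    "DynamicSeries",
    "make_phantom",
    "acquisition_mask",
    "acquire_epi",
    "acquire_reference",
    "acquire_integrated_echoes",
    "gamma_variate",
    "pyruvate_curve",
    "lactate_curve",
    "make_dynamic_series",
    "default_phantoms",
    "noise_sd_for_target_snr",
]


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseShape:
    """Ellipse in centred normalized coordinates (readout, phase-encode)."""

    center: Tuple[float, float]
    semiaxes: Tuple[float, float]
    intensity: float = 1.0

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("intensities must be non-negative")
        if min(self.semiaxes) <= 0:
            raise ValueError("semi-axes must be positive")
        for c, r in zip(self.center, self.semiaxes):
            if abs(c) + r > 1.0 + 1e-12:
                raise ValueError("shape must fit within the FOV")


@dataclass(frozen=True)
class PhantomSpec:
    """A list of ellipses summed onto an (n_readout, n_pe) grid."""

    shapes: Tuple[EllipseShape, ...]
    matrix: Tuple[int, int] = (32, 32)

    @staticmethod
    def disk(radius: float = 0.5, intensity: float = 1.0,
             center: Tuple[float, float] = (0.0, 0.0),
             matrix: Tuple[int, int] = (32, 32)) -> "PhantomSpec":
        return PhantomSpec(
            (EllipseShape(center, (radius, radius), intensity),), matrix
        )

    @staticmethod
    def dual(matrix: Tuple[int, int] = (32, 32)) -> "PhantomSpec":
        """Two disjoint disks: a small and a large source (dual-phantom case)."""
        return PhantomSpec(
            (
                EllipseShape((-0.15, -0.45), (0.18, 0.18), 1.0),
                EllipseShape((0.15, 0.3), (0.35, 0.35), 0.8),
            ),
            matrix,
        )


def make_phantom(spec: PhantomSpec) -> ImageGrid:
    """Rasterize a phantom spec into a real, non-negative image."""
    n_ro, n_pe = spec.matrix
    x = (np.arange(n_ro) - n_ro / 2) / (n_ro / 2)
    y = (np.arange(n_pe) - n_pe / 2) / (n_pe / 2)
    img = np.zeros((n_ro, n_pe))
    for s in spec.shapes:
        cx, cy = s.center
        rx, ry = s.semiaxes
        inside = ((x[:, None] - cx) / rx) ** 2 + ((y[None, :] - cy) / ry) ** 2 <= 1.0
        img += s.intensity * inside
    return ImageGrid(img)


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionParams:
    """Ground-truth corruption and sequence parameters for one acquisition.

    ``noise_sd`` is the standard deviation of the complex Gaussian noise per
    k-space sample and channel (real/imaginary), added to acquired lines
    only.  ``t2star`` (seconds, or None) applies a per-echo decay
    ``exp(-j * echo_spacing / t2star)`` in acquisition order.
    """

    coeffs: PhaseCoeffs = field(default_factory=lambda: PhaseCoeffs(0.3, 0.05))
    lines_before_center: int = 4
    noise_sd: float = 0.0
    t2star: Optional[float] = None
    seed: int = 0
    echo_spacing: float = 552e-6
    fov_readout: float = 0.04

    def __post_init__(self):
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and non-negative")
        if self.t2star is not None and self.t2star <= 0:
            raise ValueError("t2star must be positive (or None)")
        if self.lines_before_center < 0:
            raise ValueError("lines_before_center must be non-negative")


def acquisition_mask(n_pe: int, lines_before_center: int) -> np.ndarray:
    """Boolean acquired-line mask: a contiguous block from
    ``n_pe/2 - lines_before_center`` through the end of k-space (full tail).

    With n_pe=32 and 4 lines before the centre this acquires exactly 20
    lines (62.5% of k-space)."""
    first = n_pe // 2 - lines_before_center
    if first < 0:
        raise ValueError("lines_before_center exceeds half the matrix")
    mask = np.zeros(n_pe, dtype=bool)
    mask[first:] = True
    return mask


def _line_decay(k: EpiKspace, t2star: Optional[float], echo_offset: int) -> np.ndarray:
    """Per-column T2* decay factors, acquisition order, unit where unacquired."""
    d = np.ones(k.n_pe)
    if t2star is None:
        return d
    j = np.arange(k.n_pe) - k.first_acquired + echo_offset
    dec = np.exp(-j * k.echo_spacing / t2star)
    d[k.acquired_mask] = dec[k.acquired_mask]
    return d


def _add_noise(data: np.ndarray, mask: np.ndarray, sd: float,
               rng: np.random.Generator) -> None:
    if sd == 0:
        return
    shape = (data.shape[0], int(mask.sum()))
    noise = sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    data[:, mask] += noise


def acquire_epi(img: ImageGrid, p: AcquisitionParams,
                _echo_offset: int = 0) -> EpiKspace:
    """Simulate one single-shot partial-Fourier EPI readout of ``img``.

    Pipeline: forward transform -> per-line T2* decay (acquisition order)
    -> alternating phase corruption -> zero unacquired lines -> seeded
    complex Gaussian noise on acquired lines.
    """
    n_ro, n_pe = img.data.shape
    k = EpiKspace(
        data=image_to_kspace(img.data),
        echo_spacing=p.echo_spacing,
        acquired_mask=acquisition_mask(n_pe, p.lines_before_center),
        lines_before_center=p.lines_before_center,
        fov_readout=p.fov_readout,
    )
    k.data *= _line_decay(k, p.t2star, _echo_offset)[None, :]
    k = apply_phase_error(k, p.coeffs)
    rng = np.random.default_rng(p.seed)
    _add_noise(k.data, k.acquired_mask, p.noise_sd, rng)
    return k


def _projection_line(img: ImageGrid) -> np.ndarray:
    """Hybrid-space ky=0 line: the (scaled) projection of img along PE."""
    h = kspace_to_hybrid(image_to_kspace(img.data))
    return h[:, img.N // 2].copy()


def _reference_coeffs(p: AcquisitionParams, nucleus: str,
                      gamma_ratio: float, fov_ratio: float) -> PhaseCoeffs:
    """Corruption experienced by the reference nucleus.

    A proton reference sees the same eddy currents but at gamma(1H), i.e. a
    phase error 1/gamma_ratio larger; its readout FOV is fov_ratio times the
    carbon FOV, which rescales the per-normalized-coordinate beta by
    fov_ratio.  Inverse of :func:`epighost.correct.scale_reference_coeffs`.
    """
    if nucleus == "C13":
        return p.coeffs
    return PhaseCoeffs(
        p.coeffs.alpha / gamma_ratio,
        p.coeffs.beta * fov_ratio / gamma_ratio,
    )


def acquire_reference(img: ImageGrid, p: AcquisitionParams,
                      nucleus: str = "C13",
                      gamma_ratio: float = GAMMA_RATIO_C13_H1,
                      fov_ratio: float = 0.25) -> EpiKspace:
    """Simulate a reference scan: same sequence with phase-encoding off.

    Every acquired line samples ky=0 (the 1D projection of the object along
    the phase-encode direction) and carries the same alternating phase
    corruption, T2* decay and noise as the imaging readout.  For
    ``nucleus='H1'`` the corruption is the gamma/FOV-scaled proton
    equivalent; the proton object is taken as ``img`` (only the phase
    contract is modelled, not the quarter-FOV spatial remapping).
    """
    n_ro, n_pe = img.data.shape
    mask = acquisition_mask(n_pe, p.lines_before_center)
    proj = _projection_line(img)
    c = _reference_coeffs(p, nucleus, gamma_ratio, fov_ratio)

    h = np.zeros((n_ro, n_pe), dtype=complex)
    k = EpiKspace(
        data=h,
        echo_spacing=p.echo_spacing,
        acquired_mask=mask,
        lines_before_center=p.lines_before_center,
        nucleus=nucleus,
        fov_readout=p.fov_readout,
    )
    x = k.readout_coords
    theta = c.theta(x)
    decay = _line_decay(k, p.t2star, 0)
    parity = k.line_parity
    for col in np.flatnonzero(mask):
        h[:, col] = proj * decay[col] * np.exp(1j * parity[col] * theta)
    k.data = hybrid_to_kspace(h)
    k.data[:, ~mask] = 0.0
    rng = np.random.default_rng(p.seed)
    _add_noise(k.data, mask, p.noise_sd, rng)
    return k


def acquire_integrated_echoes(img: ImageGrid, p: AcquisitionParams,
                              n_echoes: int = 3) -> Tuple[np.ndarray, EpiKspace]:
    """Simulate an acquisition with integrated reference echoes.

    ``n_echoes`` non-phase-encoded echoes (alternating polarity, T2*
    decayed, hybrid-space lines of shape ``(n_readout, n_echoes)``) precede
    the imaging train, whose per-line T2* decay is advanced by
    ``n_echoes * echo_spacing`` — the SNR cost of the integrated-reference
    approach.  With ``t2star=None`` the imaging k-space is identical to
    :func:`acquire_epi` at the same seed.
    """
    if n_echoes < 2:
        raise ValueError("need at least 2 integrated echoes to estimate a phase")
    proj = _projection_line(img)
    x = readout_coords_of(img)
    theta = p.coeffs.theta(x)
    echoes = np.empty((img.data.shape[0], n_echoes), dtype=complex)
    for e in range(n_echoes):
        dec = 1.0 if p.t2star is None else math.exp(-e * p.echo_spacing / p.t2star)
        echoes[:, e] = proj * dec * np.exp(1j * ((-1) ** e) * theta)
    rng = np.random.default_rng([p.seed, 7919])  # echo noise on its own stream
    if p.noise_sd > 0:
        # noise added in the echo (k-space) domain, then viewed in hybrid space
        ke = hybrid_to_kspace(echoes)
        ke += p.noise_sd * (rng.standard_normal(ke.shape)
                            + 1j * rng.standard_normal(ke.shape))
        echoes = kspace_to_hybrid_cols(ke)
    imaging = acquire_epi(img, p, _echo_offset=n_echoes)
    return echoes, imaging


def readout_coords_of(img: ImageGrid) -> np.ndarray:
    return img.readout_coords


def kspace_to_hybrid_cols(k: np.ndarray) -> np.ndarray:
    return kspace_to_hybrid(k)


# ---------------------------------------------------------------------------
# dynamic series
# ---------------------------------------------------------------------------

def gamma_variate(t, shape: float = 3.0, scale: float = 4.0):
    """Gamma-variate bolus curve, normalized to unit peak (t in seconds)."""
    t = np.asarray(t, dtype=float)
    tp = (shape - 1.0) * scale
    peak = tp ** (shape - 1.0) * np.exp(-tp / scale)
    out = np.where(t > 0, np.power(np.clip(t, 0, None), shape - 1.0)
                   * np.exp(-t / scale) / peak, 0.0)
    return out


def pyruvate_curve(t):
    """Default pyruvate signal curve: gamma-variate, shape 3, scale 4 s."""
    return gamma_variate(t, 3.0, 4.0)


def lactate_curve(t):
    """Default lactate curve: the pyruvate family delayed 4 s, scaled 0.3."""
    return 0.3 * gamma_variate(np.asarray(t, dtype=float) - 4.0, 3.0, 4.0)


#: acquisition order of the metabolites within one TR pair
METABOLITES = ("pyruvate", "lactate")


@dataclass
class DynamicSeries:
    """Time-ordered EPI frames for two metabolites sharing one coefficient
    pair; ``times[m][i]`` is the acquisition time of ``frames[m][i]``."""

    frames: Dict[str, List[EpiKspace]]
    times: Dict[str, np.ndarray]
    amplitudes: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        shapes = {f.data.shape for fr in self.frames.values() for f in fr}
        if len(shapes) > 1:
            raise ValueError("all frames must share the same matrix")

    @property
    def metabolites(self) -> Tuple[str, ...]:
        return tuple(self.frames)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.frames.values())))

    def iter_frames(self) -> Iterator[Tuple[float, str, int, EpiKspace]]:
        """Yield (time, metabolite, index, frame) ordered by (time, metabolite)."""
        entries = [
            (float(self.times[m][i]), m, i, f)
            for m in self.frames
            for i, f in enumerate(self.frames[m])
        ]
        entries.sort(key=lambda e: (e[0], e[1]))
        return iter(entries)

    def summed(self, metabolite: str) -> EpiKspace:
        """Sum of all k-space frames of one metabolite (for summed-image search)."""
        frames = self.frames[metabolite]
        return frames[0].with_data(sum(f.data for f in frames))


def make_dynamic_series(
    phantoms: Optional[Dict[str, PhantomSpec]] = None,
    curves: Optional[Dict[str, Callable]] = None,
    p: AcquisitionParams = AcquisitionParams(),
    n_frames: int = 10,
    tr: float = 2.0,
    t_start: float = 6.0,
) -> DynamicSeries:
    """Simulate a dynamic two-metabolite series.

    Frame ``i`` of metabolite ``m`` is ``acquire_epi(curve_m(t_i) * phantom_m)``
    with per-frame seeds ``p.seed + flat_index`` (flat index in (time,
    metabolite) acquisition order: pyruvate then lactate within each TR
    pair).  All frames share ``p.coeffs``.  The default timing places the
    first frame at 6 s post injection so every frame of the delayed lactate
    curve carries signal.
    """
    if phantoms is None:
        phantoms = default_phantoms()
    if curves is None:
        curves = {"pyruvate": pyruvate_curve, "lactate": lactate_curve}
    frames: Dict[str, List[EpiKspace]] = {m: [] for m in phantoms}
    times: Dict[str, np.ndarray] = {}
    amps: Dict[str, np.ndarray] = {}
    order = [m for m in METABOLITES if m in phantoms] or sorted(phantoms)
    base_imgs = {m: make_phantom(phantoms[m]) for m in phantoms}
    for m_idx, m in enumerate(order):
        # metabolites are excited alternately: lactate trails pyruvate by tr/2
        t = t_start + tr * np.arange(n_frames) + (tr / len(order)) * m_idx
        a = np.clip(np.asarray(curves[m](t), dtype=float), 0.0, None)
        times[m] = t
        amps[m] = a
        for i in range(n_frames):
            flat = i * len(order) + m_idx
            pi = replace(p, seed=p.seed + flat)
            frames[m].append(acquire_epi(ImageGrid(a[i] * base_imgs[m].data), pi))
    return DynamicSeries(frames=frames, times=times, amplitudes=amps)


def default_phantoms(matrix: Tuple[int, int] = (32, 32)) -> Dict[str, PhantomSpec]:
    """Default objects: a body-like ellipse for pyruvate and a smaller
    tumour-like ellipse (offset within it) for lactate."""
    pyr = PhantomSpec(
        (EllipseShape((0.0, -0.05), (0.5, 0.42), 1.0),
         EllipseShape((0.2, 0.18), (0.2, 0.16), 0.6)),
        matrix,
    )
    lac = PhantomSpec(
        (EllipseShape((0.2, 0.18), (0.22, 0.18), 1.0),),
        matrix,
    )
    return {"pyruvate": pyr, "lactate": lac}


# ---------------------------------------------------------------------------
# noise calibration
# ---------------------------------------------------------------------------

_RAYLEIGH_SD = math.sqrt((4.0 - math.pi) / 2.0)  # magnitude-noise SD per channel SD


def noise_sd_for_target_snr(img: ImageGrid, p: AcquisitionParams,
                            target_snr: float,
                            object_mask: np.ndarray) -> float:
    """k-space noise SD giving a requested object SNR in the reconstruction.

    The SNR convention matches :func:`epighost.metrics.snr`: mean object
    magnitude divided by the SD of the magnitude over a noise-only region
    (Rayleigh SD = sigma * sqrt((4 - pi)/2) for per-channel image-noise SD
    sigma).  The object mean is measured on the noiseless corrupted
    reconstruction, and sigma follows exactly from the linearity of the
    inverse FFT over the acquired samples.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    noiseless = replace(p, noise_sd=0.0)
    recon = reconstruct(acquire_epi(img, noiseless))
    mean_obj = float(recon.magnitude[np.asarray(object_mask, dtype=bool)].mean())
    if mean_obj == 0:
        raise ValueError("object mask contains no signal")
    n_ro, n_pe = img.data.shape
    n_acq = int(acquisition_mask(n_pe, p.lines_before_center).sum())
    sigma_img = mean_obj / (target_snr * _RAYLEIGH_SD)
    return sigma_img * (n_ro * n_pe) / math.sqrt(n_ro * n_acq)
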