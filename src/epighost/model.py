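"""Forward model of EPI Nyquist ghosting and its inversion.

Single-shot echo planar imaging traverses k-space with a train of bipolar
readout gradients, so consecutive phase-encode lines are read under opposite
gradient polarity.  Group delays and readout-direction eddy currents then
imprint a phase error

    theta(x) = alpha + beta * x

on the data in the x–ky hybrid space (data inverse-transformed along the
readout axis only), with *alternating sign* on odd and even lines.  After the
phase-encode transform the alternating component aliases to a replica of the
object displaced by half the field of view in the phase-encode direction —
the Nyquist ghost.  For a full, noiseless acquisition the corrupted image has
the closed form

    rho_hat(x, y) = rho(x, y) * cos(theta(x)) + i * rho(x, y - N/2) * sin(theta(x))

where ``rho`` is the ideal image and ``N`` the number of phase-encode steps.
This module implements the corruption operator, zero-filled reconstruction,
the closed form (used as an independent oracle in tests), and the conjugate
correction operator.

Conventions
-----------
* Arrays are ``n_readout x n_pe``: row index = readout (x) position or kx
  sample, column index = phase-encode line.  DC sits at the matrix centre;
  all transforms use the shifted FFT convention so that the half-FOV ghost
  shift is a circular shift by exactly ``N // 2`` columns.
* ``x`` is the centred readout sample index ``x_n = n - n_readout/2``, so
  ``beta`` is in radians per readout sample.  (-pi/2, pi/2] is then the
  natural (Nyquist) range for both coefficients: ``alpha`` is periodic in
  pi outright, and a pi shift of the per-sample slope ``beta`` aliases to
  the same magnitude image displaced by half the readout FOV.  This scaling
  is also what makes the search behave as observed experimentally — one
  grid step of ``beta`` tilts the edge phase by ~N/2 grid steps, so the
  ghost-minimization objective is steep in ``beta`` and comparatively
  tolerant in ``alpha``.
* Line polarity: even-indexed lines (0-based, acquisition order) carry
  ``+theta``, odd-indexed lines ``-theta``.  With partial-Fourier sampling
  the acquisition index of stored column ``c`` is ``c - c0`` where ``c0`` is
  the first acquired column.
* The phase error is periodic in pi (a pi shift of alpha flips the sign of
  the whole k-space and leaves the magnitude image unchanged), so
  coefficients canonicalize into (-pi/2, pi/2].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "GAMMA_RATIO_C13_H1",
    "PhaseCoeffs",
    "PerLineCoeffs",
    "Coeffs2D",
    "EpiKspace",
    "ImageGrid",
    "canonicalize_phase",
    "readout_coords",
    "image_to_kspace",
    "kspace_to_image",
    "kspace_to_hybrid",
    "hybrid_to_kspace",
    "hybrid_to_image",
    "apply_phase_error",
    "reconstruct",
    "closed_form_ghost",
    "correct_with_coeffs",
]

#: gamma(13C) / gamma(1H) = 10.7084 / 42.5775 MHz/T — the factor by which a
#: proton-measured phase error must be rescaled before use on carbon data.
GAMMA_RATIO_C13_H1 = 10.7084 / 42.5775


def canonicalize_phase(phi):
    """Map phase(s) into the canonical interval (-pi/2, pi/2] modulo pi."""
    return np.pi / 2 - np.mod(np.pi / 2 - np.asarray(phi), np.pi)


def readout_coords(n_readout: int) -> np.ndarray:
    """Centred readout sample indices x_n = n - n_readout/2."""
    return np.arange(n_readout) - n_readout / 2.0


# ---------------------------------------------------------------------------
# coefficient containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseCoeffs:
    """Zero- and first-order odd/even phase-error coefficients.

    Parameters
    ----------
    alpha : float
        Zero-order phase error in radians (e.g. a B0 shift induced by a
        gradient pulse).
    beta : float
        First-order phase error in radians per readout sample (centred
        sample index), as produced by a readout-direction eddy current or a
        group delay between gradient and sampling.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("phase coefficients must be finite")

    def canonical(self) -> "PhaseCoeffs":
        """Return the equivalent pair with both values in (-pi/2, pi/2]."""
        return PhaseCoeffs(
            float(canonicalize_phase(self.alpha)),
            float(canonicalize_phase(self.beta)),
        )

    def theta(self, x: np.ndarray) -> np.ndarray:
        """Evaluate theta(x) = alpha + beta * x."""
        return self.alpha + self.beta * np.asarray(x)

    def negated(self) -> "PhaseCoeffs":
        return PhaseCoeffs(-self.alpha, -self.beta)


@dataclass(frozen=True)
class PerLineCoeffs:
    """One (alpha, beta) pair per phase-encode line (reference-scan output)."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("alpha and beta must be 1-D arrays of equal length")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)

    def __len__(self) -> int:
        return self.alpha.size

    def mean(self) -> PhaseCoeffs:
        return PhaseCoeffs(float(self.alpha.mean()), float(self.beta.mean()))


@dataclass(frozen=True)
class Coeffs2D:
    """2D-search coefficients: a scalar phase per readout column plus a
    first-order term in the phase-encode (y) direction.

    ``theta_col[n]`` subsumes ``alpha + beta_x * x_n``; ``beta_y`` multiplies
    the centred line index, adding a y-direction linear term (radians per
    phase-encode line).
    """

    theta_col: np.ndarray
    beta_y: float

    def __post_init__(self):
        t = np.asarray(self.theta_col, dtype=float)
        if t.ndim != 1:
            raise ValueError("theta_col must be 1-D (one value per readout column)")
        object.__setattr__(self, "theta_col", t)


Coefficients = Union[PhaseCoeffs, PerLineCoeffs, Coeffs2D]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class EpiKspace:
    """Complex 2D EPI k-space with acquisition metadata.

    ``data[r, c]`` is the kx sample ``r`` of phase-encode line ``c`` (stored
    centred: column ``n_pe // 2`` is ky = 0).  Acquired lines form one
    contiguous block containing the ky = 0 line; the remaining lines are
    zero-filled (62.5% partial Fourier in the study geometry: 20 of 32 lines
    with 4 lines before the centre).
    """

    data: np.ndarray
    echo_spacing: float
    acquired_mask: np.ndarray
    lines_before_center: int
    nucleus: str = "C13"
    fov_readout: float = 0.04

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("k-space data must be 2-D (n_readout x n_pe)")
        self.acquired_mask = np.asarray(self.acquired_mask, dtype=bool)
        if self.acquired_mask.shape != (self.data.shape[1],):
            raise ValueError(
                "acquired_mask length %r does not match n_pe=%d"
                % (self.acquired_mask.shape, self.data.shape[1])
            )
        idx = np.flatnonzero(self.acquired_mask)
        if idx.size == 0:
            raise ValueError("at least one line must be acquired")
        if idx[-1] - idx[0] + 1 != idx.size:
            raise ValueError("acquired lines must form one contiguous block")
        if not self.acquired_mask[self.n_pe // 2]:
            raise ValueError("acquired block must contain the ky=0 line")
        if self.lines_before_center != self.n_pe // 2 - idx[0]:
            raise ValueError(
                "lines_before_center=%d inconsistent with acquired block starting "
                "at column %d of %d" % (self.lines_before_center, idx[0], self.n_pe)
            )
        if self.nucleus not in ("C13", "H1"):
            raise ValueError("nucleus must be 'C13' or 'H1'")
        if not (self.echo_spacing > 0):
            raise ValueError("echo_spacing must be positive")

    @property
    def n_readout(self) -> int:
        return self.data.shape[0]

    @property
    def n_pe(self) -> int:
        return self.data.shape[1]

    @property
    def first_acquired(self) -> int:
        return self.n_pe // 2 - self.lines_before_center

    @property
    def line_parity(self) -> np.ndarray:
        """Polarity sign per stored column: +1 on even acquisition indices."""
        c = np.arange(self.n_pe)
        return np.where((c - self.first_acquired) % 2 == 0, 1, -1)

    @property
    def readout_coords(self) -> np.ndarray:
        return readout_coords(self.n_readout)

    def with_data(self, data: np.ndarray) -> "EpiKspace":
        return replace(self, data=np.asarray(data, dtype=complex))


@dataclass
class ImageGrid:
    """Complex reconstructed image on the centred grid.

    ``N`` (the phase-encode matrix size) equals the number of columns; a
    circular shift by ``N // 2`` columns is its own inverse, which is how the
    half-FOV ghost shift is realized.
    """

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("image data must be 2-D")

    @property
    def n_readout(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[1]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def readout_coords(self) -> np.ndarray:
        return readout_coords(self.data.shape[0])


# ---------------------------------------------------------------------------
# centred Fourier transforms
# ---------------------------------------------------------------------------

def image_to_kspace(img: np.ndarray) -> np.ndarray:
    """Centred 2D forward transform (DC at the matrix centre)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


def kspace_to_image(k: np.ndarray) -> np.ndarray:
    """Centred 2D inverse transform."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k)))


def kspace_to_hybrid(k: np.ndarray) -> np.ndarray:
    """Inverse transform along the readout axis only -> x–ky hybrid space."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(k, axes=0), axis=0), axes=0
    )


def hybrid_to_kspace(h: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft(np.fft.ifftshift(h, axes=0), axis=0), axes=0)


def hybrid_to_image(h: np.ndarray) -> np.ndarray:
    """Inverse transform along the phase-encode axis (completes the recon)."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(h, axes=1), axis=1), axes=1
    )


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def _theta_matrix(k: EpiKspace, c: Coefficients) -> np.ndarray:
    """Phase error theta evaluated on the (n_readout, n_pe) grid."""
    x = k.readout_coords
    if isinstance(c, PhaseCoeffs):
        return np.broadcast_to(c.theta(x)[:, None], (k.n_readout, k.n_pe)).copy()
    if isinstance(c, PerLineCoeffs):
        if len(c) != k.n_pe:
            raise ValueError(
                "per-line coefficients (%d) do not match n_pe=%d" % (len(c), k.n_pe)
            )
        return c.alpha[None, :] + c.beta[None, :] * x[:, None]
    if isinstance(c, Coeffs2D):
        if c.theta_col.size != k.n_readout:
            raise ValueError(
                "theta_col length %d does not match n_readout=%d"
                % (c.theta_col.size, k.n_readout)
            )
        j = np.arange(k.n_pe) - k.n_pe / 2.0
        return c.theta_col[:, None] + c.beta_y * j[None, :]
    raise TypeError("unsupported coefficient container: %r" % type(c))


def apply_phase_error(k: EpiKspace, c: PhaseCoeffs) -> EpiKspace:
    """Corrupt an ideal k-space with the alternating odd/even phase error.

    In hybrid space, line ``j`` (acquisition order) is multiplied by
    ``exp(+i * (-1)**j * theta(x))``; the data are then transformed back to
    k-space and unacquired lines are (re-)zeroed.
    """
    theta = _theta_matrix(k, c)
    phase = np.exp(1j * k.line_parity[None, :] * theta)
    h = kspace_to_hybrid(k.data) * phase
    out = hybrid_to_kspace(h)
    out[:, ~k.acquired_mask] = 0.0
    return k.with_data(out)


def reconstruct(k: EpiKspace) -> ImageGrid:
    """Zero-fill unacquired lines and apply the centred 2D inverse transform."""
    data = k.data.copy()
    data[:, ~k.acquired_mask] = 0.0
    return ImageGrid(kspace_to_image(data))


def closed_form_ghost(img: ImageGrid, c: PhaseCoeffs) -> ImageGrid:
    """Analytic Nyquist-ghost image of an ideal (full-k-space) image.

    Returns ``rho * cos(theta(x)) + i * roll(rho, N/2, pe) * sin(theta(x))``
    — the independent oracle for ``reconstruct(apply_phase_error(...))`` on a
    full, noiseless k-space.  Exact when the phase-encode matrix size is a
    multiple of 4, so that the alternating-parity modulation under centred
    FFT indexing aligns with the half-FOV shift without a global sign.
    """
    theta = c.theta(img.readout_coords)[:, None]
    shifted = np.roll(img.data, img.N // 2, axis=1)
    return ImageGrid(img.data * np.cos(theta) + 1j * shifted * np.sin(theta))


def correct_with_coeffs(k: EpiKspace, c: Coefficients) -> ImageGrid:
    """Undo the odd/even phase error and reconstruct.

    Multiplies hybrid-space line ``j`` by ``exp(-i * (-1)**j * theta)`` — the
    conjugate of the corruption phase — then reconstructs.  For ``Coeffs2D``
    the phase is ``theta_col(x) + beta_y * j`` with ``j`` the centred line
    index.
    """
    theta = _theta_matrix(k, c)
    phase = np.exp(-1j * k.line_parity[None, :] * theta)
    h = kspace_to_hybrid(k.data) * phase
    h[:, ~k.acquired_mask] = 0.0
    return ImageGrid(hybrid_to_image(h))
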