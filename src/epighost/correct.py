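"""Phase-correction coefficient estimation.

Four routes to the odd/even phase-error coefficients:

* reference scan (phase-encode gradients off): Ahn-style cumulative phase
  unwrapping of adjacent-line phase differences in hybrid space, followed by
  a magnitude-weighted linear fit, per line;
* integrated reference echoes: the same pairwise estimate on a few
  non-phase-encoded echoes prepended to the readout train, averaged into a
  single coefficient pair;
* proton reference scan: the reference estimate rescaled by the
  gyromagnetic-ratio and readout-FOV ratios before use on carbon data;
* referenceless exhaustive search: every (alpha, beta) combination on a
  grid over (-pi/2, pi/2] is applied as a correction and the pair that
  minimizes the mean magnitude in operator-selected ghost-containing bands
  is returned (1D search), optionally with an additional first-order term in
  the phase-encode direction and per-readout-column phases (2D search).

The searches are literal and exhaustive, but evaluated factorized: the
corrected image is an x-dependent linear combination of two precomputed
images (the plain reconstruction and its parity-flipped counterpart), so a
candidate costs one elementwise combine rather than an FFT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import metrics
from .model import (
    Coeffs2D,
    EpiKspace,
    ImageGrid,
    PerLineCoeffs,
    PhaseCoeffs,
    correct_with_coeffs,
    hybrid_to_image,
    kspace_to_hybrid,
)
from .simulate import DynamicSeries

__all__ = [
    "SearchConfig",
    "GhostBands",
    "LowSnrWarning",
    "UnwrapResult",
    "Search1DResult",
    "Search2DResult",
    "WorkflowResult",
    "build_ghost_bands",
    "phase_unwrap_1d",
    "estimate_from_reference",
    "estimate_from_integrated_echoes",
    "scale_reference_coeffs",
    "search_1d",
    "search_2d",
    "apply_workflow",
]


class LowSnrWarning(UserWarning):
    """Search frame SNR below the reliability floor; coefficients may be random."""


@dataclass(frozen=True)
class SearchConfig:
    """Exhaustive-search grid: ``n_steps`` evenly spaced points per
    coefficient, endpoints included, spanning (-pi/2, pi/2] by default.

    The objective is the mean magnitude over the ghost bands; ties are
    broken by smallest ``|alpha| + |beta|``, then smallest ``|beta|``.
    """

    grid_min: float = -np.pi / 2
    grid_max: float = np.pi / 2
    n_steps: int = 100

    def __post_init__(self):
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_steps)

    @property
    def step(self) -> float:
        return (self.grid_max - self.grid_min) / (self.n_steps - 1)


@dataclass(frozen=True)
class GhostBands:
    """Boolean mask of pixels treated as ghost-containing background."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("ghost bands must be a non-empty 2-D mask")
        object.__setattr__(self, "mask", m)


def build_ghost_bands(object_mask: np.ndarray, margin_rows: int = 0) -> GhostBands:
    """Bands outside the object's phase-encode extent, full readout width.

    The object ROI (drawn to include all signal sources) occupies a range of
    phase-encode lines; everything strictly before the first and strictly
    after the last object line — shrunk by ``margin_rows`` — is assumed to
    contain only ghost and noise.  An object spanning every phase-encode
    line leaves no band; the search then needs manually supplied bands.
    """
    mask = np.asarray(object_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("object mask must be a non-empty 2-D mask")
    occupied = np.flatnonzero(mask.any(axis=0))
    first, last = occupied[0], occupied[-1]
    n_pe = mask.shape[1]
    cols = np.arange(n_pe)
    band_cols = (cols < first - margin_rows) | (cols > last + margin_rows)
    if not band_cols.any():
        raise ValueError(
            "object spans all phase-encode lines; no ghost band is available "
            "— supply ghost bands manually (the search requires signal that "
            "does not cover the whole FOV)"
        )
    bands = np.zeros_like(mask)
    bands[:, band_cols] = True
    return GhostBands(bands)


# ---------------------------------------------------------------------------
# reference-based estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnwrapResult:
    """Unwrapped phase plus a flag per sample where zero magnitude forced
    the previous phase to be carried forward."""

    phase: np.ndarray
    carried: np.ndarray


def phase_unwrap_1d(phase_samples: np.ndarray,
                    magnitudes: np.ndarray) -> UnwrapResult:
    """Cumulative (Ahn-style) phase unwrapping from complex samples.

    ``phi(0) = arg(S_0)``; ``phi(n) = phi(n-1) + arg(S_n * conj(S_{n-1}))``
    with ``S_n = m_n * exp(i * p_n)``.  Immune to +-2pi wraps as long as the
    true inter-sample phase steps stay below pi.  Across a zero-magnitude
    run the last valid phase is carried forward (those samples are flagged)
    and unwrapping resumes against the last valid sample.
    """
    p = np.asarray(phase_samples, dtype=float)
    m = np.asarray(magnitudes, dtype=float)
    if p.shape != m.shape or p.ndim != 1:
        raise ValueError("phase and magnitude arrays must be equal-length 1-D")
    s = m * np.exp(1j * p)
    out = np.empty_like(p)
    carried = np.zeros_like(m, dtype=bool)
    last_valid = None  # index of last sample with signal
    phi = 0.0
    for n in range(p.size):
        if m[n] == 0:
            carried[n] = True
        elif last_valid is None:
            phi = float(np.angle(s[n]))
        else:
            phi += float(np.angle(s[n] * np.conj(s[last_valid])))
        out[n] = phi
        if m[n] > 0:
            last_valid = n
    return UnwrapResult(out, carried)


def _pair_coeffs(line_a: np.ndarray, line_b: np.ndarray, sign_a: int,
                 x: np.ndarray, threshold: float) -> PhaseCoeffs:
    """(alpha, beta) from one adjacent line pair of a reference acquisition.

    The inter-line phase difference equals ``-2 * sign_a * theta(x)`` where
    the projection magnitude is non-zero.  The unwrap is re-anchored at the
    strongest sample so that noise accumulated across the empty background
    cannot shift the zero-order term, and the linear fit is restricted to
    (and weighted by) samples above ``threshold`` of the peak magnitude.
    """
    prod = line_b * np.conj(line_a)
    mag = np.sqrt(np.abs(prod))  # ~ projection magnitude
    unwrapped = phase_unwrap_1d(np.angle(prod), np.abs(prod)).phase
    imax = int(np.argmax(mag))
    anchored = unwrapped - unwrapped[imax] + float(np.angle(prod[imax]))
    theta = -anchored / (2.0 * sign_a)
    sel = mag > threshold * mag[imax]
    if sel.sum() < 2:
        raise ValueError("too few samples above the fit-mask threshold")
    beta, alpha = np.polyfit(x[sel], theta[sel], 1, w=mag[sel])
    return PhaseCoeffs(float(alpha), float(beta)).canonical()


def estimate_from_reference(ref: EpiKspace,
                            fit_mask_threshold: float = 0.1) -> PerLineCoeffs:
    """Per-line coefficients from a reference scan (phase encoding off).

    Each adjacent acquired line pair yields one (alpha, beta) estimate,
    assigned to the first line of the pair; the last acquired line inherits
    the final pair's estimate and zero-filled lines inherit the nearest
    acquired line's estimate.
    """
    acq = np.flatnonzero(ref.acquired_mask)
    if acq.size < 2:
        raise ValueError("reference scan needs at least 2 acquired lines")
    h = kspace_to_hybrid(ref.data)
    x = ref.readout_coords
    parity = ref.line_parity
    alpha = np.full(ref.n_pe, np.nan)
    beta = np.full(ref.n_pe, np.nan)
    for c in acq[:-1]:
        est = _pair_coeffs(h[:, c], h[:, c + 1], int(parity[c]), x,
                           fit_mask_threshold)
        alpha[c], beta[c] = est.alpha, est.beta
    alpha[acq[-1]] = alpha[acq[-2]]
    beta[acq[-1]] = beta[acq[-2]]
    known = np.flatnonzero(~np.isnan(alpha))
    for c in np.flatnonzero(np.isnan(alpha)):
        nearest = known[np.argmin(np.abs(known - c))]
        alpha[c], beta[c] = alpha[nearest], beta[nearest]
    return PerLineCoeffs(alpha, beta)


def estimate_from_integrated_echoes(echoes: np.ndarray,
                                    fit_mask_threshold: float = 0.1
                                    ) -> PhaseCoeffs:
    """One averaged (alpha, beta) pair from integrated reference echoes.

    ``echoes`` are hybrid-space lines of shape (n_readout, n_echoes) in
    acquisition order (alternating polarity, echo 0 positive).
    """
    e = np.asarray(echoes, dtype=complex)
    if e.ndim != 2 or e.shape[1] < 2:
        raise ValueError("need at least 2 integrated echoes")
    n_ro, n_e = e.shape
    x = np.arange(n_ro) - n_ro / 2.0
    ests = [
        _pair_coeffs(e[:, i], e[:, i + 1], (-1) ** i, x, fit_mask_threshold)
        for i in range(n_e - 1)
    ]
    return PhaseCoeffs(
        float(np.mean([c.alpha for c in ests])),
        float(np.mean([c.beta for c in ests])),
    ).canonical()


def scale_reference_coeffs(c: Union[PhaseCoeffs, PerLineCoeffs],
                           gamma_ratio: float,
                           fov_ratio: float = 1.0
                           ) -> Union[PhaseCoeffs, PerLineCoeffs]:
    """Rescale reference-nucleus coefficients for the target nucleus.

    ``alpha -> alpha * gamma_ratio`` and ``beta -> beta * gamma_ratio /
    fov_ratio`` with ``gamma_ratio = gamma_target / gamma_reference`` and
    ``fov_ratio = FOV_reference / FOV_target`` along readout.  beta is a
    per-sample phase slope and the readout trains share one matrix size, so
    the FOV ratio converts the reference's spatial slope onto the target
    grid; a quarter-FOV proton readout at the same gradient then nearly
    cancels the gyromagnetic scaling (0.2515 / 0.25 ~= 1.006).
    """
    if gamma_ratio <= 0 or fov_ratio <= 0:
        raise ValueError("ratios must be positive")
    if isinstance(c, PerLineCoeffs):
        return PerLineCoeffs(c.alpha * gamma_ratio,
                             c.beta * gamma_ratio / fov_ratio)
    return PhaseCoeffs(c.alpha * gamma_ratio, c.beta * gamma_ratio / fov_ratio)


# ---------------------------------------------------------------------------
# exhaustive searches
# ---------------------------------------------------------------------------

def _search_images(k: EpiKspace) -> Tuple[np.ndarray, np.ndarray]:
    """Precompute the two images whose x-dependent linear combination gives
    every candidate-corrected image: A (plain reconstruction) and B (the
    parity-flipped reconstruction, i.e. the half-FOV alias component)."""
    data = k.data.copy()
    data[:, ~k.acquired_mask] = 0.0
    h = kspace_to_hybrid(data)
    s = k.line_parity[None, :]
    return hybrid_to_image(h), hybrid_to_image(h * s)


def _check_bands(k: EpiKspace, bands: GhostBands) -> None:
    if bands.mask.shape != k.data.shape:
        raise ValueError("ghost-band mask shape does not match the k-space")


def _tie_break_pairs(alphas: np.ndarray, betas: np.ndarray,
                     obj: np.ndarray) -> Tuple[int, int]:
    """Index of the minimizing grid point; exact ties resolved by smallest
    |alpha|+|beta|, then |beta|, then (alpha, beta)."""
    m = obj.min()
    cand = np.argwhere(obj == m)
    keys = [
        (abs(alphas[ia]) + abs(betas[ib]), abs(betas[ib]),
         alphas[ia], betas[ib], ia, ib)
        for ia, ib in cand
    ]
    best = min(keys)
    return best[4], best[5]


@dataclass
class Search1DResult:
    """1D-search output: the chosen pair plus diagnostics."""

    coeffs: PhaseCoeffs
    corrected: ImageGrid
    objective: np.ndarray  # (n_alpha, n_beta) band-mean magnitude surface
    alphas: np.ndarray
    betas: np.ndarray


def search_1d(k: EpiKspace, bands: GhostBands,
              cfg: SearchConfig = SearchConfig()) -> Search1DResult:
    """Exhaustive grid search for the (alpha, beta) pair minimizing the mean
    magnitude over the ghost bands.

    Every ``n_steps x n_steps`` combination is evaluated (endpoints
    included); the corrected image of the winning pair and the full
    objective surface are returned for diagnostics.
    """
    _check_bands(k, bands)
    A, B = _search_images(k)
    rows, cols = np.nonzero(bands.mask)
    Af, Bf = A[rows, cols], B[rows, cols]
    x = k.readout_coords
    grid = cfg.grid
    obj = np.empty((grid.size, grid.size))
    bx = np.outer(grid, x)  # (n_beta, n_readout)
    for ia, a in enumerate(grid):
        th = (a + bx)[:, rows]  # (n_beta, n_pix)
        vals = np.cos(th) * Af[None, :] - 1j * np.sin(th) * Bf[None, :]
        obj[ia] = np.abs(vals).mean(axis=1)
    ia, ib = _tie_break_pairs(grid, grid, obj)
    coeffs = PhaseCoeffs(float(grid[ia]), float(grid[ib]))
    return Search1DResult(coeffs, correct_with_coeffs(k, coeffs), obj, grid, grid)


@dataclass
class Search2DResult:
    """2D-search output: per-readout-column phases plus the y-direction term."""

    coeffs: Coeffs2D
    corrected: ImageGrid
    flagged_rows: List[int]
    beta_y_objective: np.ndarray  # total band magnitude per beta_y candidate


def search_2d(k: EpiKspace, bands: GhostBands,
              cfg: SearchConfig = SearchConfig()) -> Search2DResult:
    """Exhaustive 2D search: an outer grid over the phase-encode-direction
    first-order term ``beta_y`` and, for each candidate, an independent grid
    search of the scalar phase of every readout column that minimizes the
    band magnitude within that column.

    Readout columns with no band pixels cannot be optimized locally; they
    inherit the global 1D solution and are reported in ``flagged_rows``.
    """
    _check_bands(k, bands)
    data = k.data.copy()
    data[:, ~k.acquired_mask] = 0.0
    h0 = kspace_to_hybrid(data)
    s = k.line_parity
    n_ro, n_pe = data.shape
    j_norm = np.arange(n_pe) - n_pe / 2.0
    grid = cfg.grid
    # preference order for per-column ties: smallest |theta|, then theta
    order = np.lexsort((grid, np.abs(grid)))
    g_ord = grid[order]

    band_rows = [np.flatnonzero(bands.mask[r]) for r in range(n_ro)]
    flagged = [r for r, c in enumerate(band_rows) if c.size == 0]
    active = [r for r, c in enumerate(band_rows) if c.size > 0]
    uniform = len(active) == n_ro and all(
        np.array_equal(band_rows[r], band_rows[active[0]]) for r in active
    )

    by_pref = sorted(grid, key=lambda b: (abs(b), b))
    best_total = np.inf
    best_by = by_pref[0]
    best_theta = np.zeros(n_ro)
    by_obj = np.empty(grid.size)
    by_obj_index = {float(b): i for i, b in enumerate(grid)}
    cos_g, sin_g = np.cos(g_ord), np.sin(g_ord)
    for by in by_pref:
        phase = np.exp(-1j * s * by * j_norm)[None, :]
        h2 = h0 * phase
        A2 = hybrid_to_image(h2)
        B2 = hybrid_to_image(h2 * s[None, :])
        theta_row = np.zeros(n_ro)
        if uniform:
            cols = band_rows[active[0]]
            vals = np.abs(
                cos_g[:, None, None] * A2[None, :, cols]
                - 1j * sin_g[:, None, None] * B2[None, :, cols]
            ).sum(axis=2)  # (n_grid, n_ro)
            pick = vals.argmin(axis=0)
            theta_row[:] = g_ord[pick]
            total = float(vals[pick, np.arange(n_ro)].sum())
        else:
            total = 0.0
            for r in active:
                cols = band_rows[r]
                vals = np.abs(
                    np.outer(cos_g, A2[r, cols])
                    - 1j * np.outer(sin_g, B2[r, cols])
                ).sum(axis=1)
                i = int(vals.argmin())
                theta_row[r] = g_ord[i]
                total += float(vals[i])
        by_obj[by_obj_index[float(by)]] = total
        if total < best_total:
            best_total = total
            best_by = float(by)
            best_theta = theta_row
    if flagged:
        fallback = search_1d(k, bands, cfg).coeffs
        x = k.readout_coords
        for r in flagged:
            best_theta[r] = fallback.alpha + fallback.beta * x[r]
    coeffs = Coeffs2D(best_theta, best_by)
    return Search2DResult(coeffs, correct_with_coeffs(k, coeffs), flagged, by_obj)


# ---------------------------------------------------------------------------
# dynamic-series workflow
# ---------------------------------------------------------------------------

@dataclass
class WorkflowResult:
    coeffs: PhaseCoeffs
    images: Dict[str, List[ImageGrid]]
    search_frame: Tuple[str, Union[int, str]]
    search_snr: float
    search: Search1DResult


def _frame_snr(frame: EpiKspace, object_mask: np.ndarray,
               noise_mask: np.ndarray) -> float:
    from .model import reconstruct
    mag = reconstruct(frame).magnitude
    return metrics.snr(mag, object_mask, noise_mask)


def apply_workflow(series: DynamicSeries, object_mask: np.ndarray,
                   cfg: SearchConfig = SearchConfig(),
                   frame_selector: Union[str, Tuple[str, int]] = "peak-lactate",
                   snr_floor: float = 4.7,
                   bands: Optional[GhostBands] = None) -> WorkflowResult:
    """Search once, correct everything.

    Selects a search frame (default: the lactate frame with the highest
    object SNR; alternatives: the summed pyruvate or lactate k-space, or an
    explicit ``(metabolite, index)``), runs the 1D exhaustive search on it,
    and applies the winning coefficients to every frame of every metabolite.
    A search frame with object SNR below ``snr_floor`` (default 4.7, the
    observed reliability threshold) triggers a warning — the coefficients
    from such frames tend to be random — but the search still runs.
    """
    if not series.frames or series.n_frames == 0:
        raise ValueError("series is empty")
    if bands is None:
        bands = build_ghost_bands(object_mask)
    rois = metrics.RoiSet.from_object_mask(object_mask)
    noise_mask = rois.noise_mask

    if isinstance(frame_selector, tuple):
        met, idx = frame_selector
        k_search = series.frames[met][idx]
        frame_id: Tuple[str, Union[int, str]] = (met, idx)
        sel_snr = _frame_snr(k_search, object_mask, noise_mask)
    elif frame_selector == "peak-lactate":
        frames = series.frames["lactate"]
        snrs = [_frame_snr(f, object_mask, noise_mask) for f in frames]
        idx = int(np.argmax(snrs))
        k_search, frame_id, sel_snr = frames[idx], ("lactate", idx), snrs[idx]
    elif frame_selector in ("sum-pyruvate", "sum-lactate"):
        met = frame_selector.split("-", 1)[1]
        k_search = series.summed(met)
        frame_id = (met, "sum")
        sel_snr = _frame_snr(k_search, object_mask, noise_mask)
    else:
        raise ValueError("unknown frame selector: %r" % (frame_selector,))

    if sel_snr < snr_floor:
        warnings.warn(
            "search-frame object SNR %.2f is below the reliability floor %.2f; "
            "the searched coefficients may be random" % (sel_snr, snr_floor),
            LowSnrWarning,
        )
    result = search_1d(k_search, bands, cfg)
    images = {
        m: [correct_with_coeffs(f, result.coeffs) for f in series.frames[m]]
        for m in series.frames
    }
    return WorkflowResult(result.coeffs, images, frame_id, sel_snr, result)
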