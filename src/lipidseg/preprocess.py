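"""Spectral preprocessing: alignment, TIC normalization, average-spectrum
peak picking and datacube reduction.

The chain mirrors the standard Orbitrap-MSI reduction: spectra are
aligned (rigid per-pixel ppm shift maximizing cross-correlation with the
cohort mean, two passes), normalized to unit total ion current, summed
into an average spectrum, peaks above a fraction of the base peak are
picked from that average, and the cube is reduced to a pixels x peaks
feature matrix by taking the maximum intensity within a ppm tolerance of
each peak centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .cube import SpectraCube

__all__ = [
    "AlignmentResult", "AverageSpectrum", "PeakList", "FeatureMatrix",
    "align_spectra", "tic_normalize", "tissue_mask", "average_spectrum",
    "pick_peaks", "reduce_cube", "preprocess_cube",
]

log = logging.getLogger(__name__)


@dataclass
class AlignmentResult:
    shifts_ppm: np.ndarray          # estimated per-pixel rigid shift
    zero_pixels: np.ndarray         # bool: all-zero spectrum, shift forced to 0
    saturated: np.ndarray           # bool: estimate hit the +/- max_shift bound
    max_shift_ppm: float
    passes: int


@dataclass
class AverageSpectrum:
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class PeakList:
    """Peak centres picked from the average spectrum."""

    mz: np.ndarray
    intensity: np.ndarray           # apex intensity in the average spectrum
    threshold_fraction: float = 0.005

    def __post_init__(self):
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z must be strictly increasing")

    def __len__(self):
        return len(self.mz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})


@dataclass
class FeatureMatrix:
    """Reduced pixels x peaks intensity matrix."""

    values: np.ndarray              # (n_pixels, n_peaks)
    coords: np.ndarray              # (n_pixels, 2)
    peak_mz: np.ndarray             # (n_peaks,)
    shape: tuple[int, int]
    tol_ppm: float = 5.0
    columns: list = field(default_factory=list)   # optional species names

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("feature matrix entries must be non-negative")
        if self.values.shape != (len(self.coords), len(self.peak_mz)):
            raise ValueError("feature matrix shape mismatch")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def to_frame(self) -> pd.DataFrame:
        cols = self.columns if self.columns else [f"{m:.4f}" for m in self.peak_mz]
        idx = pd.MultiIndex.from_arrays([self.coords[:, 0], self.coords[:, 1]],
                                        names=["row", "col"])
        return pd.DataFrame(self.values, index=idx, columns=cols)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(values=self.values[mask], coords=self.coords[mask],
                             peak_mz=self.peak_mz, shape=self.shape,
                             tol_ppm=self.tol_ppm, columns=list(self.columns))


def _resample_at_shift(mz: np.ndarray, y: np.ndarray, shift_ppm: float,
                       spline: CubicSpline | None = None) -> np.ndarray:
    """Evaluate spectrum y at mz*(1+shift) -> removes a +shift ppm drift.

    Cubic-spline resampling: linear interpolation of Gaussian peaks on a
    few-ppm grid scallops the cross-correlation objective and biases the
    shift estimate by a sizeable fraction of the grid step.
    """
    if spline is None:
        spline = CubicSpline(mz, y, extrapolate=False)
    out = spline(mz * (1.0 + shift_ppm * 1e-6))
    return np.clip(np.nan_to_num(out, nan=0.0), 0.0, None)


def align_spectra(cube: SpectraCube, max_shift_ppm: float = 10.0,
                  step_ppm: float = 0.5, passes: int = 2):
    """Rigid per-pixel ppm alignment against the cohort mean spectrum.

    For each pixel the shift in [-max_shift_ppm, +max_shift_ppm] maximizing
    the cross-correlation with the running mean spectrum is found on a
    ``step_ppm`` grid and refined by parabolic interpolation; intensities
    are then resampled onto the shared axis at the corrected positions.
    Returns ``(aligned_cube, AlignmentResult)``.
    """
    if max_shift_ppm <= 0:
        raise ValueError("max_shift_ppm must be > 0")
    if cube.n_pixels == 0:
        raise ValueError("empty cube")
    mz = cube.mz
    inten = cube.intensities
    tics = inten.sum(axis=1)
    zero = tics <= 0
    cand = np.arange(-max_shift_ppm, max_shift_ppm + step_ppm / 2, step_ppm)

    shifts = np.zeros(cube.n_pixels)
    aligned = inten.copy()
    for _ in range(passes):
        ref = aligned[~zero].mean(axis=0) if (~zero).any() else np.zeros_like(mz)
        nrm = np.linalg.norm(ref)
        if nrm == 0:
            break
        ref = ref / nrm
        # reference shifted by +d matches a pixel drifted by +d
        ref_spline = CubicSpline(mz, ref, extrapolate=False)
        refbank = np.vstack([_resample_at_shift(mz, ref, -d, spline=ref_spline)
                             for d in cand])
        scores = inten @ refbank.T                     # (n_pixels, n_cand)
        best = np.argmax(scores, axis=1)
        est = cand[best].astype(float)
        interior = (best > 0) & (best < len(cand) - 1)
        b = best[interior]
        y0 = scores[interior, b - 1]
        y1 = scores[interior, b]
        y2 = scores[interior, b + 1]
        denom = y0 - 2 * y1 + y2
        offs = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / denom, 0.0)
        est[interior] = cand[b] + np.clip(offs, -1.0, 1.0) * step_ppm
        est[zero] = 0.0
        shifts = est
        for i in range(cube.n_pixels):
            if not zero[i] and shifts[i] != 0.0:
                aligned[i] = _resample_at_shift(mz, inten[i], shifts[i])
            else:
                aligned[i] = inten[i]
    saturated = np.abs(shifts) >= max_shift_ppm - step_ppm / 2
    saturated &= ~zero
    out = cube.copy()
    out.intensities = aligned
    out.metadata = {**cube.metadata, "aligned": True}
    return out, AlignmentResult(shifts_ppm=shifts, zero_pixels=zero,
                                saturated=saturated, max_shift_ppm=max_shift_ppm,
                                passes=passes)


def tic_normalize(obj):
    """Scale each pixel so its summed intensity is 1.

    Works on a :class:`SpectraCube` or a :class:`FeatureMatrix`.  All-zero
    pixels are left as zeros and flagged rather than raising.  Returns
    ``(normalized, tics, zero_flags)``.
    """
    if isinstance(obj, FeatureMatrix):
        tics = obj.values.sum(axis=1)
        zero = tics <= 0
        vals = np.where(zero[:, None], obj.values, obj.values / np.where(zero, 1.0, tics)[:, None])
        out = FeatureMatrix(values=vals, coords=obj.coords.copy(), peak_mz=obj.peak_mz,
                            shape=obj.shape, tol_ppm=obj.tol_ppm, columns=list(obj.columns))
        return out, tics, zero
    cube: SpectraCube = obj
    tics = cube.tic()
    zero = tics <= 0
    out = cube.copy()
    out.intensities = np.where(zero[:, None], cube.intensities,
                               cube.intensities / np.where(zero, 1.0, tics)[:, None])
    out.metadata = {**cube.metadata, "tic_normalized": True}
    return out, tics, zero


def tissue_mask(tics: np.ndarray, method: str = "relative",
                threshold: float = 0.05, q: float = 0.05) -> np.ndarray:
    """Tissue/background discrimination from the per-pixel TIC.

    ``relative``: keep pixels with TIC >= threshold * median(TIC).
    ``quantile``: keep pixels with TIC >= the q-quantile of the TIC
    distribution.
    """
    tics = np.asarray(tics, float)
    if method == "relative":
        cut = threshold * np.median(tics[tics > 0]) if (tics > 0).any() else 0.0
    elif method == "quantile":
        cut = np.quantile(tics, q)
    else:
        raise ValueError(f"unknown tissue-mask method {method!r}")
    return tics >= max(cut, np.finfo(float).tiny)


def average_spectrum(cube: SpectraCube, mask: np.ndarray | None = None) -> AverageSpectrum:
    """Pointwise mean spectrum over the (optionally masked) pixels on the
    shared m/z grid.  Intended to run after alignment and normalization."""
    if cube.n_pixels == 0:
        raise ValueError("empty cube")
    inten = cube.intensities if mask is None else cube.intensities[mask]
    if inten.shape[0] == 0:
        raise ValueError("mask selects no pixels")
    return AverageSpectrum(mz=cube.mz.copy(), intensity=inten.mean(axis=0))


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def pick_peaks(avg: AverageSpectrum, threshold_fraction: float = 0.005,
               smooth_window: int = 3) -> PeakList:
    """Local maxima of the average spectrum above a fraction of the base peak.

    Maxima are located on a (by default 3-point moving-average) smoothed
    trace; the apex intensity and the intensity threshold use the raw
    spectrum, so the published cutoff (intensity >= threshold_fraction x
    strongest peak) applies to actual intensities.
    """
    if not 0 <= threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in [0, 1]")
    y = np.asarray(avg.intensity, float)
    if len(y) == 0 or np.all(y <= 0) or np.ptp(y) == 0:
        return PeakList(mz=np.empty(0), intensity=np.empty(0),
                        threshold_fraction=threshold_fraction)
    ys = _moving_average(y, smooth_window)
    interior = np.arange(1, len(y) - 1)
    is_max = (ys[interior] > ys[interior - 1]) & (ys[interior] > ys[interior + 1])
    apex = interior[is_max]
    cutoff = threshold_fraction * y.max()
    apex = apex[y[apex] >= cutoff]
    return PeakList(mz=avg.mz[apex], intensity=y[apex],
                    threshold_fraction=threshold_fraction)


def reduce_cube(cube: SpectraCube, peaklist: PeakList, tol_ppm: float = 5.0) -> FeatureMatrix:
    """Extract, per pixel, the maximum intensity within +/- tol_ppm of every
    peak centre.  Each spectral sample feeds at most one peak; where the
    tolerance windows of neighbouring peaks overlap, samples go to the
    nearest centre (a warning is logged)."""
    if len(peaklist) == 0:
        raise ValueError("peaklist is empty")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    mz = cube.mz
    centers = peaklist.mz
    lo_bound = centers * (1.0 - tol_ppm * 1e-6)
    hi_bound = centers * (1.0 + tol_ppm * 1e-6)
    if np.any(hi_bound[:-1] > lo_bound[1:]):
        log.warning("overlapping peak windows at tol_ppm=%.3g; samples assigned "
                    "to the nearest centre", tol_ppm)
        mid = 0.5 * (centers[:-1] + centers[1:])
        lo_bound[1:] = np.maximum(lo_bound[1:], mid)
        hi_bound[:-1] = np.minimum(hi_bound[:-1], mid)
    values = np.zeros((cube.n_pixels, len(centers)))
    for p in range(len(centers)):
        i0 = np.searchsorted(mz, lo_bound[p], side="left")
        i1 = np.searchsorted(mz, hi_bound[p], side="right")
        if i1 > i0:
            values[:, p] = cube.intensities[:, i0:i1].max(axis=1)
    return FeatureMatrix(values=values, coords=cube.coords.copy(), peak_mz=centers.copy(),
                         shape=cube.shape, tol_ppm=tol_ppm)


def preprocess_cube(cube: SpectraCube, max_shift_ppm: float = 10.0,
                    threshold_fraction: float = 0.005, tol_ppm: float = 5.0,
                    mask_method: str = "relative", mask_threshold: float = 0.05):
    """Full reduction chain: align -> TIC normalize -> tissue mask ->
    average -> pick peaks -> reduce.  Returns a dict with every
    intermediate product."""
    aligned, align_res = align_spectra(cube, max_shift_ppm=max_shift_ppm)
    normalized, tics, zero = tic_normalize(aligned)
    mask = tissue_mask(tics, method=mask_method, threshold=mask_threshold) & ~zero
    avg = average_spectrum(normalized, mask=mask)
    peaks = pick_peaks(avg, threshold_fraction=threshold_fraction)
    features = reduce_cube(normalized, peaks, tol_ppm=tol_ppm).subset(mask)
    return {
        "aligned": aligned, "alignment": align_res, "normalized": normalized,
        "tics": tics, "tissue_mask": mask, "average": avg, "peaks": peaks,
        "features": features,
    }
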