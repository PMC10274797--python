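"""Beam localization, diffused reflectance profile (DRP), ROI selection and
the contrast-normalized intensity autocorrelation g2(t).

The ensemble for g2 comprises every pixel inside a circular ROI concentric
with the beam centre (radius = the 1/e radius of the DRP) and every pair of
frames separated by a given lag.  The correlator evaluates the exact
all-pairs average at a pseudo-logarithmic subset of integer lags using
per-pixel FFT autocorrelation, which is algebraically identical to the direct
O(T^2) sum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.fft import next_fast_len, irfft, rfft

logger = logging.getLogger("shears")


@dataclass
class DRProfile:
    """Radial diffused-reflectance profile about the beam centre."""

    radial_bins: np.ndarray  # bin centres, pixels
    mean_intensity: np.ndarray  # azimuthally averaged time-mean counts
    beam_center: tuple  # (row, col), sub-pixel
    one_over_e_radius: float  # pixels
    background: float = 0.0  # subtracted background level, counts
    radial_bins_m: Optional[np.ndarray] = None  # bin centres in metres if known

    def __post_init__(self) -> None:
        if self.one_over_e_radius <= 0:
            raise ValueError("one_over_e_radius must be positive")


@dataclass
class CorrelationCurve:
    """Lag times and intensity autocorrelation with per-lag ensemble sizes."""

    lags: np.ndarray  # seconds, strictly increasing, first lag 0
    g2: np.ndarray
    n_pairs: np.ndarray
    normalized: bool = True  # contrast-normalized (g2(0) == 2)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if self.lags[0] != 0:
            raise ValueError("first lag must be 0")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.n_pairs < 1):
            raise ValueError("every retained lag needs n_pairs >= 1")
        if self.normalized and abs(self.g2[0] - 2.0) > 1e-9:
            raise ValueError("a contrast-normalized curve must have g2(0) = 2")


def compute_drp(series, background_annulus_frac: float = 0.05) -> DRProfile:
    """Locate the beam and build the radial DRP from the time-averaged frame.

    The beam centre is the intensity-weighted centroid; the profile is the
    azimuthal average about it; the 1/e radius is where the
    background-subtracted profile first falls below 1/e of its peak
    (sub-bin linear interpolation).  Background is the mean of the outermost
    5% radial annulus.
    """
    mean_frame = np.asarray(series.frames, dtype=np.float64).mean(axis=2)
    total = mean_frame.sum()
    if total <= 0:
        raise ValueError("no DRP decay detected: empty image")
    rows, cols = np.indices(mean_frame.shape)
    r0 = float((rows * mean_frame).sum() / total)
    c0 = float((cols * mean_frame).sum() / total)

    dist = np.hypot(rows - r0, cols - c0)
    r_max = dist.max()
    bins = np.arange(0, int(np.ceil(r_max)) + 1)
    idx = np.clip(dist.astype(int), 0, len(bins) - 1)
    sums = np.bincount(idx.ravel(), weights=mean_frame.ravel(), minlength=len(bins))
    counts = np.bincount(idx.ravel(), minlength=len(bins))
    good = counts > 0
    profile = np.full(len(bins), np.nan)
    profile[good] = sums[good] / counts[good]
    radii = bins.astype(float) + 0.5
    radii, profile = radii[good], profile[good]

    # background from the outermost annulus
    n_bg = max(1, int(round(background_annulus_frac * len(radii))))
    background = float(profile[-n_bg:].mean())
    prof_bs = profile - background

    peak_i = int(np.argmax(prof_bs))
    peak = prof_bs[peak_i]
    if peak <= 0:
        raise ValueError("no DRP decay detected")
    thresh = peak / np.e
    below = np.nonzero(prof_bs[peak_i:] < thresh)[0]
    if len(below) == 0:
        raise ValueError("no DRP decay detected: profile never falls below 1/e")
    j = below[0] + peak_i
    # interpolate between bins j-1 and j
    if j == 0:
        radius = radii[0]
    else:
        y0, y1 = prof_bs[j - 1], prof_bs[j]
        frac = (y0 - thresh) / (y0 - y1) if y1 != y0 else 0.0
        radius = float(radii[j - 1] + frac * (radii[j] - radii[j - 1]))

    half_short = min(mean_frame.shape) / 2.0
    if radius > half_short:
        warnings.warn(
            f"1/e radius {radius:.1f} px exceeds half the short frame dimension; clipping",
            stacklevel=2,
        )
        radius = half_short

    radial_m = None
    pitch = getattr(series, "pixel_pitch", None)
    if pitch:
        radial_m = radii * pitch
    return DRProfile(
        radial_bins=radii,
        mean_intensity=profile,
        beam_center=(r0, c0),
        one_over_e_radius=radius,
        background=background,
        radial_bins_m=radial_m,
    )


def select_roi(drp: DRProfile, frame_shape) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the DRP 1/e radius of
    the beam centre; clips (with a warning) when the disc leaves the frame."""
    rows, cols = np.indices(frame_shape)
    r0, c0 = drp.beam_center
    dist = np.hypot(rows - r0, cols - c0)
    mask = dist <= drp.one_over_e_radius
    # warn when the requested disc is not fully contained in the frame
    if (
        r0 - drp.one_over_e_radius < -0.5
        or c0 - drp.one_over_e_radius < -0.5
        or r0 + drp.one_over_e_radius > frame_shape[0] - 0.5
        or c0 + drp.one_over_e_radius > frame_shape[1] - 0.5
    ):
        warnings.warn("ROI radius extends beyond the frame; mask clipped", stacklevel=2)
    return mask


def multitau_lags(n_frames: int, per_octave: int = 16, max_lag_frac: float = 0.1) -> np.ndarray:
    """Pseudo-logarithmic (multi-tau style) integer lag set.

    ~``per_octave`` lags per octave from 1 frame up to ``n_frames *
    max_lag_frac``, always including lag 0.
    """
    max_lag = max(1, int(n_frames * max_lag_frac))
    n_oct = np.log2(max_lag) if max_lag > 1 else 0
    exps = np.arange(0, int(np.ceil(n_oct * per_octave)) + 1)
    lags = np.unique(np.round(2.0 ** (exps / per_octave)).astype(np.int64))
    lags = lags[lags <= max_lag]
    return np.concatenate([[0], lags])


def envelope_flatten(frames: np.ndarray, profile_smooth: int = 5) -> np.ndarray:
    """Estimate the stationary intensity envelope for flat-fielding.

    The envelope is reconstructed from the azimuthally averaged radial
    profile of the time-averaged frame about its centroid (the DRP is
    isotropic): azimuthal plus temporal pooling suppresses residual speckle
    without distorting the radial shape the way 2-D smoothing would.
    """
    mean_img = np.asarray(frames, dtype=np.float64).mean(axis=2)
    total = mean_img.sum()
    if total <= 0:
        return np.ones_like(mean_img)
    rows, cols = np.indices(mean_img.shape)
    r0 = (rows * mean_img).sum() / total
    c0 = (cols * mean_img).sum() / total
    dist = np.hypot(rows - r0, cols - c0)
    idx = dist.astype(int)
    n_bins = idx.max() + 1
    sums = np.bincount(idx.ravel(), weights=mean_img.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    prof = sums / np.maximum(counts, 1)
    if profile_smooth > 1:
        kernel = np.ones(profile_smooth) / profile_smooth
        prof = np.convolve(np.pad(prof, profile_smooth // 2, mode="edge"), kernel, "valid")[: n_bins]
    env = np.interp(dist.ravel(), np.arange(n_bins) + 0.5, prof).reshape(mean_img.shape)
    return np.maximum(env, max(env.max(), 1e-300) * 1e-6)


def _g2_raw_sums(X: np.ndarray, lags: np.ndarray, pixel_norm: bool, chunk: int = 256):
    """Exact all-pairs g2_raw at the given integer lags via per-pixel FFT
    autocorrelation (algebraically identical to the direct O(T^2) sum).

    ``pixel_norm`` normalizes each pixel's correlation by its own front/back
    mean intensities before pixel averaging (cancelling the static DRP
    envelope); otherwise one global normalization is applied.
    """
    npix, T = X.shape
    nfft = next_fast_len(2 * T)
    n_t0 = (T - lags).astype(np.float64)
    if pixel_norm:
        acc = np.zeros(len(lags))
        for lo in range(0, npix, chunk):
            block = X[lo : lo + chunk]
            F = rfft(block, nfft, axis=1)
            ac = irfft(F * np.conj(F), nfft, axis=1)[:, lags]
            cs = np.concatenate(
                [np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1
            )
            front = cs[:, T - lags] / n_t0
            back = (cs[:, [T]] - cs[:, lags]) / n_t0
            acc += ((ac / n_t0) / (front * back)).sum(axis=0)
        return acc / npix
    acc = np.zeros(T)
    for lo in range(0, npix, chunk):
        block = X[lo : lo + chunk]
        F = rfft(block, nfft, axis=1)
        ac = irfft(F * np.conj(F), nfft, axis=1)[:, :T]
        acc += ac.sum(axis=0)
    S = X.sum(axis=0)
    cs = np.concatenate([[0.0], np.cumsum(S)])
    n_pairs = npix * n_t0
    front = (cs[T - lags] - cs[0]) / n_pairs
    back = (cs[T] - cs[lags]) / n_pairs
    return (acc[lags] / n_pairs) / (front * back)


def compute_g2(
    series,
    roi_mask: np.ndarray,
    lags: Optional[Sequence[int]] = None,
    normalization: str = "auto",
) -> CorrelationCurve:
    """Contrast-normalized ensemble g2(t) over a pixel ROI.

    ``g2_raw(t) = <I(t0) I(t0+t)> / (<I(t0)> <I(t0+t)>)`` over all ROI pixels
    and all admissible frame pairs; the returned curve is
    ``(g2_raw(t) - 1) / (g2_raw(0) - 1) + 1`` where the lag-0 point uses the
    same-frame second moment, forcing g2(0) = 2 exactly.

    normalization:
      - ``"pixel"``: each ensemble member is normalized by its own pixel's
        front/back mean intensities.  This cancels the static DRP envelope
        (whose spatial variance would otherwise leave a non-decaying
        baseline in g2) and is the accurate choice for decorrelating
        samples.
      - ``"ensemble"``: one global normalization after flat-fielding by the
        radial envelope estimate; required for static samples, whose
        speckle contrast is purely spatial.
      - ``"auto"`` (default): ``"pixel"`` unless the per-pixel temporal
        contrast is negligible (frozen sample), then ``"ensemble"``.
    """
    frames = series.frames
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    if normalization not in ("auto", "pixel", "ensemble"):
        raise ValueError(f"unknown normalization '{normalization}'")
    T = frames.shape[2]
    X = np.asarray(frames[roi_mask], dtype=np.float64)  # (npix, T)
    npix = X.shape[0]
    if np.any(X.mean(axis=1) <= 0):
        raise ValueError("ROI contains fully dark pixels; shrink the ROI")

    if lags is None:
        int_lags = multitau_lags(T)
    else:
        int_lags = np.unique(np.asarray(lags, dtype=np.int64))
        if int_lags[0] != 0:
            int_lags = np.concatenate([[0], int_lags])
    drop = int_lags >= T
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} lag(s) >= n_frames ({T})", stacklevel=2
        )
        int_lags = int_lags[~drop]

    mode = normalization
    if mode in ("auto", "pixel"):
        g2_raw = _g2_raw_sums(X, int_lags, pixel_norm=True)
        if mode == "auto" and g2_raw[0] - 1.0 < 0.05:
            logger.info("compute_g2: static sample detected; ensemble normalization")
            mode = "ensemble"
        else:
            mode = "pixel"
    if mode == "ensemble":
        env = envelope_flatten(frames)
        Xf = X / env[roi_mask][:, None]
        g2_raw = _g2_raw_sums(Xf, int_lags, pixel_norm=False)

    n_pairs = npix * (T - int_lags).astype(np.float64)
    contrast = g2_raw[0] - 1.0
    if contrast <= 1e-12:
        raise ValueError("zero speckle contrast: temporally constant series")
    g2 = (g2_raw - 1.0) / contrast + 1.0
    return CorrelationCurve(
        lags=int_lags / series.frame_rate,
        g2=g2,
        n_pairs=n_pairs,
        normalized=True,
    )


def g2_direct(
    frames: np.ndarray,
    roi_mask: np.ndarray,
    lags: Sequence[int],
    pixel_norm: bool = True,
) -> np.ndarray:
    """Brute-force O(T^2) all-pairs raw correlator (reference implementation).

    Returns ``g2_raw`` (not contrast normalized, no flat-fielding) at the
    given integer lags.
    """
    X = np.asarray(frames[np.asarray(roi_mask, dtype=bool)], dtype=np.float64)
    T = X.shape[1]
    out = np.empty(len(lags))
    for i, d in enumerate(lags):
        a = X[:, : T - d] if d else X
        b = X[:, d:] if d else X
        if pixel_norm:
            per_px = (a * b).mean(axis=1) / (a.mean(axis=1) * b.mean(axis=1))
            out[i] = per_px.mean()
        else:
            out[i] = (a * b).mean() / (a.mean() * b.mean())
    return out


def normalize_contrast(curve: CorrelationCurve) -> CorrelationCurve:
    """Contrast-normalize a raw correlation curve so that g2(0) = 2."""
    contrast = curve.g2[0] - 1.0
    if contrast <= 1e-12:
        raise ValueError("zero speckle contrast")
    g2 = (curve.g2 - 1.0) / contrast + 1.0
    return CorrelationCurve(
        lags=curve.lags, g2=g2, n_pairs=curve.n_pairs, normalized=True
    )
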