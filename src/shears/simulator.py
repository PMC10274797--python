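"""Forward models: GSER-consistent MSDs, synthetic correlation curves and
full synthetic speckle movies with known ground truth.

Movies realize a prescribed field correlation ``g1(t) = exp(-gamma (k^2
msd(t))^zeta)`` by evolving per-pixel phasors with stationary-increment
Gaussian phases (fractional-Brownian type), low-pass filtering a white
complex field to the requested speckle size, shaping the intensity with a
Gaussian diffuse-reflectance envelope, and optionally adding shot noise and
bit-depth quantization.  Everything is deterministic under a seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.special import gamma as gamma_function

from .correlogram import CorrelationCurve
from .optics_calibration import OpticalCalibration
from .rheology_core import BOLTZMANN, GSERContext, MSDCurve
from .speckle_io import SpeckleSeries, log_seed

logger = logging.getLogger("shears")

MODEL_KINDS = ("newtonian", "maxwell", "powerlaw", "generalized_maxwell", "piecewise_msd")


@dataclass
class RheoModel:
    """A prescribed viscoelastic model with thermodynamic context."""

    kind: str
    params: dict
    temperature: float = 295.0
    particle_radius: float = 1.5e-6

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind '{self.kind}'")
        p = self.params
        if self.kind == "newtonian" and p["eta"] <= 0:
            raise ValueError("viscosity must be positive")
        if self.kind == "maxwell" and (p["g0"] <= 0 or p["tau"] <= 0):
            raise ValueError("maxwell parameters must be positive")
        if self.kind == "powerlaw":
            if p["prefactor"] <= 0:
                raise ValueError("power-law prefactor must be positive")
            if not 0 < p["exponent"] < 1:
                raise ValueError("power-law exponent must be in (0, 1)")
        if self.kind == "generalized_maxwell":
            for g0, tau in p["modes"]:
                if g0 <= 0 or tau <= 0:
                    raise ValueError("generalized-maxwell modes must be positive")
            if p.get("solvent_viscosity", 0.0) < 0:
                raise ValueError("solvent viscosity must be non-negative")
        if self.kind == "piecewise_msd":
            knots = np.asarray(p["knots"], dtype=float)
            if knots.shape[0] < 2 or np.any(knots <= 0):
                raise ValueError("piecewise_msd needs >= 2 positive (t, msd) knots")
            slopes = np.diff(np.log(knots[:, 1])) / np.diff(np.log(knots[:, 0]))
            if np.any(slopes < -1e-9) or np.any(slopes > 1 + 1e-9):
                raise ValueError("piecewise_msd knot slopes must lie in [0, 1]")

    # -- constructors -------------------------------------------------------
    @classmethod
    def newtonian(cls, eta: float, **kw) -> "RheoModel":
        return cls("newtonian", {"eta": eta}, **kw)

    @classmethod
    def maxwell(cls, g0: float, tau: float, **kw) -> "RheoModel":
        return cls("maxwell", {"g0": g0, "tau": tau}, **kw)

    @classmethod
    def powerlaw(cls, prefactor: float, exponent: float, **kw) -> "RheoModel":
        return cls("powerlaw", {"prefactor": prefactor, "exponent": exponent}, **kw)

    @classmethod
    def generalized_maxwell(
        cls, modes: Sequence[Tuple[float, float]], solvent_viscosity: float = 0.0, **kw
    ) -> "RheoModel":
        return cls(
            "generalized_maxwell",
            {"modes": [tuple(m) for m in modes], "solvent_viscosity": solvent_viscosity},
            **kw,
        )

    @classmethod
    def piecewise_msd(cls, knots: Sequence[Tuple[float, float]], **kw) -> "RheoModel":
        return cls("piecewise_msd", {"knots": [tuple(k) for k in knots]}, **kw)

    @classmethod
    def from_yaml(cls, path) -> "RheoModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kw = {}
        for key in ("temperature", "particle_radius"):
            if key in raw:
                kw[key] = float(raw[key])
        return cls(raw["kind"], raw["params"], **kw)

    @property
    def context(self) -> GSERContext:
        return GSERContext(
            temperature=self.temperature, particle_radius=self.particle_radius
        )

    def modulus(self, omega: np.ndarray) -> np.ndarray:
        """Analytic complex modulus G*(omega), where a closed form exists."""
        omega = np.asarray(omega, dtype=float)
        s = 1j * omega
        if self.kind == "newtonian":
            return s * self.params["eta"]
        if self.kind == "maxwell":
            g0, tau = self.params["g0"], self.params["tau"]
            return g0 * s * tau / (1.0 + s * tau)
        if self.kind == "powerlaw":
            A, a0 = self.params["prefactor"], self.params["exponent"]
            return A * omega ** a0 * np.exp(1j * math.pi * a0 / 2.0)
        if self.kind == "generalized_maxwell":
            out = s * self.params.get("solvent_viscosity", 0.0)
            for g0, tau in self.params["modes"]:
                out = out + g0 * s * tau / (1.0 + s * tau)
            return out
        raise ValueError(f"no closed-form modulus for kind '{self.kind}'")


@dataclass
class InstrumentModel:
    """Synthetic camera / optics description."""

    shape: Tuple[int, int] = (64, 64)  # pixels
    frame_rate: float = 10_000.0  # Hz
    n_frames: int = 20_000
    speckle_size: float = 3.5  # pixels per speckle (FWHM of intensity autocov)
    beta: float = 1.0  # coherence factor
    drp_scale: float = 12.0  # Gaussian envelope sigma, pixels
    shot_noise: bool = False
    bit_depth: int = 16
    wavelength: float = 637e-9  # metres
    pixel_pitch: float = 20e-6  # metres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_size < 2.0:
            raise ValueError("speckle size below 2 px undersamples the speckle")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "InstrumentModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# MSD generation
# ---------------------------------------------------------------------------


def msd_from_model(model: RheoModel, times: np.ndarray) -> MSDCurve:
    """Ground-truth MSD of a thermal probe in the given model medium.

    Closed forms for newtonian / powerlaw / maxwell (from the creep
    compliance J(t): msd = kB T J(t) / (pi a)); generalized-maxwell via the
    algebraic GSER applied to the analytic modulus; piecewise models
    interpolate the knot list log-log.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be positive and sorted")
    kB, T, a = BOLTZMANN, model.temperature, model.particle_radius
    pref = kB * T / (math.pi * a)
    p = model.params
    if model.kind == "newtonian":
        msd = pref * times / p["eta"]
    elif model.kind == "powerlaw":
        a0 = p["exponent"]
        msd = pref * times ** a0 / (p["prefactor"] * gamma_function(1.0 + a0))
    elif model.kind == "maxwell":
        msd = pref * (1.0 + times / p["tau"]) / p["g0"]
    elif model.kind == "generalized_maxwell":
        omega = 1.0 / times
        g = model.modulus(omega)
        alpha = np.clip(2.0 / math.pi * np.angle(g), 0.0, 1.0)
        msd = pref / (gamma_function(1.0 + alpha) * np.abs(g))
    elif model.kind == "piecewise_msd":
        knots = np.asarray(p["knots"], dtype=float)
        logm = np.interp(
            np.log(times), np.log(knots[:, 0]), np.log(knots[:, 1])
        )
        # extrapolate with the edge slopes rather than np.interp's clamping
        sl_lo = (math.log(knots[1, 1]) - math.log(knots[0, 1])) / (
            math.log(knots[1, 0]) - math.log(knots[0, 0])
        )
        sl_hi = (math.log(knots[-1, 1]) - math.log(knots[-2, 1])) / (
            math.log(knots[-1, 0]) - math.log(knots[-2, 0])
        )
        lo = times < knots[0, 0]
        hi = times > knots[-1, 0]
        logm[lo] = math.log(knots[0, 1]) + sl_lo * (np.log(times[lo]) - math.log(knots[0, 0]))
        logm[hi] = math.log(knots[-1, 1]) + sl_hi * (np.log(times[hi]) - math.log(knots[-1, 0]))
        msd = np.exp(logm)
    else:  # pragma: no cover
        raise ValueError(model.kind)
    return MSDCurve(times=times, msd=msd)


# ---------------------------------------------------------------------------
# g2 synthesis
# ---------------------------------------------------------------------------


def synthesize_g2(
    msd: MSDCurve, calibration: OpticalCalibration, beta: float = 1.0
) -> CorrelationCurve:
    """Raw (un-normalized) g2 from an MSD: ``g2 - 1 = beta exp(-2 gamma (k^2
    msd)^zeta)`` on the MSD's lag grid, with the lag-0 point set to the
    same-frame limit ``g2(0) - 1 = beta``."""
    if np.any(msd.msd < 0):
        raise ValueError("msd must be non-negative")
    gam, zet, k = calibration.gamma, calibration.zeta, calibration.k
    x = (k ** 2) * msd.msd
    decay = np.exp(-2.0 * gam * np.where(x > 0, x, 0.0) ** zet)
    g2 = 1.0 + beta * decay
    lags = np.concatenate([[0.0], msd.times])
    g2 = np.concatenate([[1.0 + beta], g2])
    return CorrelationCurve(
        lags=lags, g2=g2, n_pairs=np.ones(len(lags)), normalized=False
    )


# ---------------------------------------------------------------------------
# movie synthesis
# ---------------------------------------------------------------------------


def _increment_autocov(D: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-lag phase increments whose partial sums have
    structure function D (D[0] = 0)."""
    n = len(D) - 1  # number of increments
    c = np.empty(n)
    c[0] = D[1]
    if n > 1:
        m = np.arange(1, n)
        c[1:] = 0.5 * (D[m + 1] - 2.0 * D[m] + D[m - 1])
    return c


def _sample_stationary_increments(
    c: np.ndarray, n_series: int, rng: np.random.Generator
) -> np.ndarray:
    """Circulant-embedding (Davies-Harte) sampling of ``n_series``
    independent stationary Gaussian sequences with autocovariance ``c``.
    Slightly negative embedding eigenvalues are clipped to zero."""
    n = len(c)
    if n == 1:
        return rng.standard_normal((n_series, 1)) * math.sqrt(max(c[0], 0.0))
    emb = np.concatenate([c, c[-2:0:-1]])  # length M = 2n - 2
    M = len(emb)
    lam = np.fft.fft(emb).real
    neg = lam < 0
    if neg.any():
        frac = -lam[neg].sum() / max(lam[~neg].sum(), 1e-300)
        if frac > 1e-6:
            warnings.warn(
                f"circulant embedding clipped {frac:.2e} of total spectral mass",
                stacklevel=2,
            )
        lam = np.maximum(lam, 0.0)
    # real part of FFT(z * sqrt(lam / M)) has autocovariance exactly c
    scale = np.sqrt(lam / M)
    z = rng.standard_normal((n_series, M)) + 1j * rng.standard_normal((n_series, M))
    seq = np.fft.fft(z * scale, axis=1)
    return np.ascontiguousarray(seq.real[:, :n])


def _structure_function(
    msd: MSDCurve, calibration: OpticalCalibration, n_frames: int, dt: float
) -> np.ndarray:
    """Phase structure function D(j) = 2 gamma (k^2 msd(j dt))^zeta at integer
    frame lags, log-log interpolating (and edge-extrapolating) the MSD."""
    gam, zet, k = calibration.gamma, calibration.zeta, calibration.k
    lags = np.arange(1, n_frames) * dt
    t = msd.times
    m = msd.msd
    if np.all(m <= 0):
        return np.zeros(n_frames)
    pos = m > 0
    logt, logm = np.log(t[pos]), np.log(m[pos])
    out = np.interp(np.log(lags), logt, logm)
    if len(logt) > 1:
        sl_lo = (logm[1] - logm[0]) / (logt[1] - logt[0])
        sl_hi = (logm[-1] - logm[-2]) / (logt[-1] - logt[-2])
        lo = np.log(lags) < logt[0]
        hi = np.log(lags) > logt[-1]
        out[lo] = logm[0] + sl_lo * (np.log(lags[lo]) - logt[0])
        out[hi] = logm[-1] + sl_hi * (np.log(lags[hi]) - logt[-1])
    msd_j = np.exp(out)
    D = np.concatenate([[0.0], 2.0 * gam * ((k ** 2) * msd_j) ** zet])
    return D


def synthesize_speckle_movie(
    msd: MSDCurve,
    calibration: OpticalCalibration,
    instrument: InstrumentModel,
    _pixel_chunk: int = 256,
) -> SpeckleSeries:
    """Generate a synthetic speckle movie whose ensemble statistics follow
    the prescribed MSD through the forward g2 model.

    The per-pixel field is ``W exp(i phi(t))`` (W a static circular complex
    Gaussian reflectivity, phi a stationary-increment Gaussian process with
    structure function ``2 gamma (k^2 msd)^zeta``), low-pass filtered to the
    requested pixels-per-speckle, shaped by a Gaussian DRP envelope, reduced
    to coherence beta by a static incoherent background, then optionally
    shot-noised and quantized.
    """
    H, W = instrument.shape
    T = int(instrument.n_frames)
    dt = 1.0 / instrument.frame_rate
    rng = np.random.default_rng(instrument.seed)
    log_seed("synthesize_speckle_movie", instrument.seed)

    D = _structure_function(msd, calibration, T, dt)
    frozen = not np.any(D > 0)

    npix = H * W
    # static complex reflectivity
    refl = (rng.standard_normal(npix) + 1j * rng.standard_normal(npix)) / math.sqrt(2)

    # phases (npix, T), phi(0) = 0 per pixel
    phases = np.zeros((npix, T), dtype=np.float32)
    if not frozen:
        c = _increment_autocov(D)
        for lo in range(0, npix, _pixel_chunk):
            hi = min(lo + _pixel_chunk, npix)
            inc = _sample_stationary_increments(c, hi - lo, rng)
            phases[lo:hi, 1:] = np.cumsum(inc, axis=1, dtype=np.float64).astype(
                np.float32
            )

    # spatial low-pass kernel (speckle size = FWHM of intensity autocovariance)
    sigma_k = instrument.speckle_size / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    kernel_hat = np.exp(-2.0 * (math.pi ** 2) * (sigma_k ** 2) * (fy ** 2 + fx ** 2))

    # Gaussian intensity envelope about the frame centre
    r0, c0 = (H - 1) / 2.0, (W - 1) / 2.0
    rows, cols = np.indices((H, W))
    env = np.exp(
        -((rows - r0) ** 2 + (cols - c0) ** 2) / (2.0 * instrument.drp_scale ** 2)
    )
    amp_env = np.sqrt(env)

    full_scale = 2 ** instrument.bit_depth - 1
    # mean speckle intensity at the beam centre targets ~20% of full scale
    target_mean = 0.2 * full_scale

    frames = np.empty((H, W, T), dtype=np.float64)
    chunk_t = max(1, int(2e7 // npix))
    refl_img = refl.reshape(H, W)
    for lo in range(0, T, chunk_t):
        hi = min(lo + chunk_t, T)
        ph = phases[:, lo:hi].reshape(H, W, hi - lo)
        field = refl_img[:, :, None] * np.exp(1j * ph)
        field = np.fft.ifft2(
            np.fft.fft2(field, axes=(0, 1)) * kernel_hat[:, :, None], axes=(0, 1)
        )
        frames[:, :, lo : hi] = np.abs(field) ** 2
    del phases
    mean_int = frames.mean()
    frames *= amp_env[:, :, None] ** 2

    # coherence reduction: static incoherent background with the same envelope
    if instrument.beta < 1.0:
        bg = mean_int * (1.0 / math.sqrt(instrument.beta) - 1.0)
        frames += bg * env[:, :, None]

    scale = target_mean / (mean_int * (1.0 if instrument.beta == 1.0 else 1.0 / math.sqrt(instrument.beta)))
    frames *= scale
    if instrument.shot_noise:
        frames = rng.poisson(frames).astype(np.float64)
    counts = np.clip(np.round(frames), 0, full_scale)
    dtype = np.uint8 if instrument.bit_depth <= 8 else np.uint16
    return SpeckleSeries(
        frames=counts.astype(dtype),
        frame_rate=instrument.frame_rate,
        exposure=dt,
        wavelength=instrument.wavelength,
        pixel_pitch=instrument.pixel_pitch,
        bit_depth=instrument.bit_depth,
    )


def measure_speckle_size(series: SpeckleSeries, n_frames: int = 10) -> float:
    """Mean speckle size: FWHM (pixels) of the spatial intensity
    autocovariance averaged over the first ``n_frames`` frames.

    The slowly varying diffuse-reflectance envelope would add a broad
    pedestal to the autocovariance, so each frame is first flattened by a
    smoothed leave-one-out estimate of the mean-intensity map (the frames
    must therefore be mutually decorrelated for an unbiased envelope).
    """
    from scipy.ndimage import gaussian_filter

    H, W = series.shape
    n = min(n_frames, series.n_frames)
    if n < 2:
        raise ValueError("need at least 2 frames to estimate the envelope")
    stack = np.asarray(series.frames[:, :, :n], dtype=np.float64)
    total = stack.sum(axis=2)
    acov = np.zeros((H, W))
    for j in range(n):
        env = gaussian_filter((total - stack[:, :, j]) / (n - 1), 4.0)
        flat = stack[:, :, j] / np.maximum(env, env.max() * 1e-3)
        flat -= flat.mean()
        F = np.fft.fft2(flat)
        acov += np.fft.ifft2(F * np.conj(F)).real
    acov = np.fft.fftshift(acov / n)
    cy, cx = H // 2, W // 2
    peak = acov[cy, cx]
    # average the two in-axis cuts for the FWHM
    widths = []
    for cut in (acov[cy, cx:], acov[cy:, cx]):
        below = np.nonzero(cut < peak / 2.0)[0]
        if len(below) == 0:
            continue
        j = below[0]
        y0, y1 = cut[j - 1], cut[j]
        frac = (y0 - peak / 2.0) / (y0 - y1)
        widths.append(2.0 * (j - 1 + frac))
    if not widths:
        raise ValueError("autocovariance never falls below half maximum")
    return float(np.mean(widths))


# ---------------------------------------------------------------------------
# analytic spectrum construction (planted ground truth)
# ---------------------------------------------------------------------------


def _blended_loglog(
    logw: np.ndarray,
    anchor: Tuple[float, float],
    slopes: Sequence[float],
    breaks: Sequence[float],
    blend_width: float,
) -> np.ndarray:
    """Piecewise power law in log-log space with softplus-blended slope
    changes; returns log10 of the curve."""
    slopes = list(slopes)
    breaks = [math.log10(b) for b in breaks]
    if len(slopes) != len(breaks) + 1:
        raise ValueError("need one more slope than breaks")
    w = blend_width

    def raw(x):
        y = slopes[0] * x
        for s0, s1, b in zip(slopes[:-1], slopes[1:], breaks):
            # softplus ramp: local slope glides from s0 to s1 around b
            y = y + (s1 - s0) * w * np.logaddexp(0.0, (x - b) / w)
        return y

    x0 = math.log10(anchor[0])
    y = raw(logw)
    y0 = raw(np.array([x0]))[0]
    return math.log10(anchor[1]) + (y - y0)


def synthetic_spectrum(
    omega: np.ndarray,
    storage_anchor: Tuple[float, float],
    storage_slopes: Sequence[float],
    storage_breaks: Sequence[float],
    loss_anchor: Tuple[float, float],
    loss_slopes: Sequence[float],
    loss_breaks: Sequence[float],
    blend_width: float = 0.12,
    context: Optional[GSERContext] = None,
):
    """Construct a GSER-consistent planted spectrum from blended power laws.

    G' and G'' are built independently as smooth piecewise power laws of
    omega; |G*| and alpha follow from the phase relation
    ``tan(pi alpha / 2) = G''/G'``.  Returns ``(ViscoSpectrum, AlphaCurve)``
    whose MSD field is filled via the inverse algebraic GSER so the pair can
    be pushed through any pipeline stage.
    """
    from .rheology_core import AlphaCurve, ViscoSpectrum

    context = context or GSERContext()
    omega = np.asarray(omega, dtype=float)
    logw = np.log10(omega)
    gp = 10.0 ** _blended_loglog(logw, storage_anchor, storage_slopes, storage_breaks, blend_width)
    gpp = 10.0 ** _blended_loglog(logw, loss_anchor, loss_slopes, loss_breaks, blend_width)
    gmag = np.hypot(gp, gpp)
    alpha = 2.0 / math.pi * np.arctan2(gpp, gp)
    kB, T, a = context.boltzmann, context.temperature, context.particle_radius
    msd = kB * T / (math.pi * a * gamma_function(1.0 + alpha) * gmag)
    spectrum = ViscoSpectrum(
        omega=omega,
        g_storage=gp,
        g_loss=gpp,
        g_mag=gmag,
        alpha=alpha,
        valid=np.ones(len(omega), dtype=bool),
    )
    curve = AlphaCurve(
        omega=omega,
        alpha=alpha,
        alpha_raw=alpha.copy(),
        msd=msd,
        low_confidence=np.zeros(len(omega), dtype=bool),
    )
    return spectrum, curve
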