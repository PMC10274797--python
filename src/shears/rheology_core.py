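"""From g2(t) to the viscoelastic spectrum.

Implements the empirical inversion of the correlation curve to the mean
square displacement, the local log-log slope alpha(omega) with its
resampling / rolling-regression / smoothing numerics (30 points per decade,
7-point regression window, 15-point moving average), and the algebraic
generalized Stokes-Einstein relation

    |G*(omega)| = kB T / (pi a Gamma(1 + alpha) <dr^2(1/omega)>)
    G' = |G*| cos(pi alpha / 2),   G'' = |G*| sin(pi alpha / 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.special import gamma as gamma_function

logger = logging.getLogger("shears")

BOLTZMANN = 1.380649e-23  # J/K, exact (SI 2019)

POINTS_PER_DECADE = 30
REGRESSION_WINDOW = 7
SMOOTHING_WINDOW = 15
DEFAULT_NOISE_FLOOR = 0.03


@dataclass
class MSDCurve:
    """Time-dependent mean square displacement with a validity mask."""

    times: np.ndarray  # seconds
    msd: np.ndarray  # m^2
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(self.msd[self.valid] < 0):
            raise ValueError("MSD must be non-negative at valid points")

    def valid_slice(self) -> "MSDCurve":
        return MSDCurve(times=self.times[self.valid], msd=self.msd[self.valid])


@dataclass
class AlphaCurve:
    """Local MSD log-log slope on a log-spaced omega grid (omega = 1/t).

    ``alpha`` is the smoothed, [0, 1]-clamped slope used by the GSER;
    ``alpha_raw`` is the unsmoothed regression output kept for diagnostics.
    ``msd`` holds the MSD resampled onto the same grid, and
    ``low_confidence`` flags the shrunken edge windows.
    """

    omega: np.ndarray  # rad/s, ascending, 30 points/decade
    alpha: np.ndarray
    alpha_raw: np.ndarray
    msd: np.ndarray  # m^2, resampled at t = 1/omega
    low_confidence: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega grid must be strictly increasing")
        if np.any((self.alpha < 0) | (self.alpha > 1)):
            raise ValueError("clamped alpha must lie in [0, 1]")

    @property
    def resampled_msd(self) -> MSDCurve:
        return MSDCurve(times=1.0 / self.omega[::-1], msd=self.msd[::-1]).valid_slice()


@dataclass
class GSERContext:
    """Physical constants entering the GSER."""

    temperature: float = 295.0  # K
    particle_radius: float = 1.5e-6  # m
    boltzmann: float = BOLTZMANN

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.particle_radius <= 0:
            raise ValueError("particle_radius must be positive")


@dataclass
class ViscoSpectrum:
    """Frequency-dependent storage/loss/magnitude moduli with validity."""

    omega: np.ndarray  # rad/s
    g_storage: np.ndarray  # Pa
    g_loss: np.ndarray  # Pa
    g_mag: np.ndarray  # Pa
    alpha: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        v = self.valid
        mag2 = self.g_storage[v] ** 2 + self.g_loss[v] ** 2
        if mag2.size and not np.allclose(mag2, self.g_mag[v] ** 2, rtol=1e-12):
            raise ValueError("|G*|^2 must equal G'^2 + G''^2")
        if np.any(self.g_storage[v] < 0) or np.any(self.g_loss[v] < 0):
            raise ValueError("moduli must be non-negative at valid points")


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def mask_decorrelated(
    corr, absolute_floor: float = DEFAULT_NOISE_FLOOR
) -> np.ndarray:
    """Validity mask over the correlation curve's nonzero lags.

    A lag is marked invalid when ``g2 - 1`` has sunk below
    ``max(absolute_floor, 3 * tail std)``, the tail std being estimated over
    the last decade of lags (where, for decaying signals, only noise
    remains).
    """
    y = corr.g2 - 1.0
    lags = corr.lags
    tail = lags >= lags[-1] / 10.0
    tail_sd = float(np.std(y[tail])) if tail.sum() >= 3 else 0.0
    threshold = max(absolute_floor, 3.0 * tail_sd)
    mask = y >= threshold
    mask[0] = True  # lag 0 is definitionally correlated
    return mask


def invert_msd(
    corr,
    calibration,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    use_tail_estimate: bool = True,
) -> MSDCurve:
    """Invert a contrast-normalized g2 curve to the MSD.

    For every nonzero lag with ``g2 - 1`` inside ``(noise_floor, 1]``:

        k^2 <dr^2> = (-ln(g2 - 1) / (2 gamma))^(1/zeta)

    Points outside that range are masked invalid; the retained points are the
    longest contiguous run of lags (the validity interval must be
    contiguous).
    """
    if not corr.normalized:
        raise ValueError("invert_msd requires a contrast-normalized curve")
    y = corr.g2[1:] - 1.0
    times = corr.lags[1:]
    if use_tail_estimate:
        floor_mask = mask_decorrelated(corr, noise_floor)[1:]
    else:
        floor_mask = y > noise_floor
    ok = floor_mask & (y > 0) & (y <= 1.0)
    if not ok.any():
        raise ValueError("fully decorrelated or static signal: no invertible lags")
    ok = _longest_run(ok)

    gam, zet, k = calibration.gamma, calibration.zeta, calibration.k
    k2msd = np.full(y.shape, np.nan)
    yy = y[ok]
    k2msd[ok] = (-np.log(yy) / (2.0 * gam)) ** (1.0 / zet)
    msd = k2msd / k ** 2
    msd[~ok] = np.nan
    return MSDCurve(times=times, msd=np.where(ok, msd, 0.0), valid=ok)


def _longest_run(mask: np.ndarray) -> np.ndarray:
    """Keep only the longest contiguous True run of a boolean mask."""
    best_lo = best_hi = 0
    lo = None
    for i, m in enumerate(np.concatenate([mask, [False]])):
        if m and lo is None:
            lo = i
        elif not m and lo is not None:
            if i - lo > best_hi - best_lo:
                best_lo, best_hi = lo, i
            lo = None
    out = np.zeros_like(mask)
    out[best_lo:best_hi] = True
    return out


# ---------------------------------------------------------------------------
# alpha(omega)
# ---------------------------------------------------------------------------


def _rolling_slope(logt: np.ndarray, logy: np.ndarray, half: int) -> np.ndarray:
    """Least-squares slope of logy vs logt over a centred window of width
    2*half+1, shrinking symmetrically at the edges (uniform grid assumed)."""
    n = len(logt)
    out = np.empty(n)
    for i in range(n):
        m = min(half, i, n - 1 - i)
        if m == 0:
            m = 1 if 0 < i < n - 1 else 0
        if m == 0:
            # one-sided 2-point slope at the extreme ends
            j = 1 if i == 0 else n - 2
            out[i] = (logy[i] - logy[j]) / (logt[i] - logt[j])
            continue
        sl = slice(i - m, i + m + 1)
        x = logt[sl] - logt[i]
        y = logy[sl]
        out[i] = np.dot(x, y - y.mean()) / np.dot(x, x)
    return out


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetrically shrinking edge windows."""
    half = window // 2
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        m = min(half, i, n - 1 - i)
        out[i] = y[i - m : i + m + 1].mean()
    return out


def compute_alpha(
    msd: MSDCurve,
    points_per_decade: int = POINTS_PER_DECADE,
    regression_window: int = REGRESSION_WINDOW,
    smoothing_window: int = SMOOTHING_WINDOW,
) -> AlphaCurve:
    """Local power-law exponent of the MSD on a log-omega grid.

    (i) resample log-MSD onto a log-spaced omega grid (omega = 1/t) at 30
    points per decade; (ii) slope of the least-squares line of log-MSD vs
    log-t over a 7-point window centred at t = 1/omega; (iii) smooth with a
    15-point centred moving average; (iv) clamp to [0, 1].
    """
    cur = msd.valid_slice()
    t = cur.times
    y = cur.msd
    keep = (t > 0) & (y > 0)
    t, y = t[keep], y[keep]
    if len(t) < regression_window:
        raise ValueError(
            f"need at least {regression_window} valid MSD points, got {len(t)}"
        )
    span = t.max() / t.min()
    if span < 10.0:
        raise ValueError("valid MSD must span at least one decade in time")

    # exact 1/points_per_decade log steps upward from omega = 1/t_max
    n_decades = math.log10(span)
    n_pts = int(math.floor(n_decades * points_per_decade)) + 1
    omega = (1.0 / t.max()) * 10.0 ** (np.arange(n_pts) / points_per_decade)
    t_grid = 1.0 / omega[::-1]  # ascending times
    logt = np.log10(t_grid)
    logy = np.interp(logt, np.log10(t), np.log10(y))

    half = regression_window // 2
    slope_t = _rolling_slope(logt, logy, half)  # on ascending-t grid
    alpha_raw_t = slope_t
    alpha_raw = alpha_raw_t[::-1]  # onto ascending-omega order
    smoothed = _moving_average(alpha_raw, smoothing_window)

    n_clamped = int(np.sum((smoothed < 0) | (smoothed > 1)))
    if n_clamped:
        logger.info("compute_alpha: clamped %d alpha point(s) into [0, 1]", n_clamped)
    alpha = np.clip(smoothed, 0.0, 1.0)

    low_conf = np.zeros(n_pts, dtype=bool)
    edge = max(half, smoothing_window // 2)
    low_conf[:edge] = True
    low_conf[-edge:] = True

    msd_rs = 10.0 ** logy[::-1]  # aligned with ascending omega
    return AlphaCurve(
        omega=omega,
        alpha=alpha,
        alpha_raw=alpha_raw,
        msd=msd_rs,
        low_confidence=low_conf,
    )


# ---------------------------------------------------------------------------
# GSER
# ---------------------------------------------------------------------------


def gser(
    msd: MSDCurve,
    alpha: AlphaCurve,
    context: GSERContext,
    band: Optional[Tuple[float, float]] = None,
) -> ViscoSpectrum:
    """Algebraic GSER on the resampled grid.

    ``msd`` must be sampled at t = 1/omega for the alpha grid (as produced by
    :func:`compute_alpha`).  ``band = (omega_lo, omega_hi)`` crops validity to
    the physically measurable window ``1/tau < omega < F_s``.
    """
    omega = alpha.omega
    msd_vals = msd.msd[::-1] if msd.times[0] < msd.times[-1] else msd.msd
    if len(msd_vals) != len(omega):
        raise ValueError("msd and alpha are not on the same omega grid")
    t_expected = 1.0 / omega
    t_given = msd.times[::-1] if msd.times[0] < msd.times[-1] else msd.times
    if not np.allclose(t_given, t_expected, rtol=1e-9):
        raise ValueError("msd times do not match 1/omega of the alpha grid")

    a_vals = alpha.alpha
    kB, T, a = context.boltzmann, context.temperature, context.particle_radius
    g_mag = kB * T / (math.pi * a * gamma_function(1.0 + a_vals) * msd_vals)
    phase = math.pi * a_vals / 2.0
    g_storage = g_mag * np.cos(phase)
    g_loss = g_mag * np.sin(phase)

    valid = np.isfinite(g_mag) & (msd_vals > 0)
    if band is not None:
        lo, hi = band
        valid &= (omega > lo) & (omega < hi)
    return ViscoSpectrum(
        omega=omega,
        g_storage=g_storage,
        g_loss=g_loss,
        g_mag=g_mag,
        alpha=a_vals,
        valid=valid,
    )


def gser_transform_oracle(
    times: np.ndarray, msd: np.ndarray, omega: np.ndarray, context: GSERContext
) -> np.ndarray:
    """Independent numerical-transform GSER evaluation (test oracle).

    Computes the unilateral Laplace transform of the MSD by direct numerical
    integration on a dense log-time grid, evaluates the modulus magnitude

        |G*(omega)| = kB T / (pi a omega MSD~(s))|_{s = omega}

    and assigns the phase from the local log-log slope of the transform-based
    modulus.  This is an integral-transform path wholly independent of the
    pointwise algebraic route used in production; kept for cross-checks only.
    The supplied time grid must generously bracket 1/omega for every
    requested frequency.
    """
    kB, T, a = context.boltzmann, context.temperature, context.particle_radius
    times = np.asarray(times, dtype=float)
    msd = np.asarray(msd, dtype=float)
    logt = np.log(times)
    mags = np.empty(len(omega))
    for i, w in enumerate(omega):
        # dt = t dlog t; integrand decays exponentially for t >> 1/w
        laplace = np.trapezoid(msd * np.exp(-w * times) * times, logt)
        mags[i] = kB * T / (math.pi * a * w * laplace)
    slope = np.gradient(np.log(mags), np.log(omega))
    phase = math.pi * np.clip(slope, 0.0, 1.0) / 2.0
    return mags * np.exp(1j * phase)
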