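"""Monte Carlo photon transport and the (gamma, zeta) calibration of the
empirical g2 <-> MSD inversion.

The inversion ``g2 - 1 = exp(-2 gamma (k^2 <dr^2>)^zeta)`` interpolates
between the single-scattering (DLS) limit ``(gamma, zeta) = (2/3, 1)`` and
the strongly diffusive backscattering (DWS) limit ``(5/3, 0.5)``.  For an
arbitrary turbid sample the pair is obtained by simulating backscattered
photon path lengths in a semi-infinite medium (Henyey-Greenstein scattering,
matched or mismatched boundary), synthesizing the field autocorrelation
through the DWS path-integral kernel and fitting the stretched-exponential
form.  A small lookup table over (mu_s', mu_a, g) makes repeated queries
cheap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.optimize import least_squares

from .speckle_io import log_seed

logger = logging.getLogger("shears")

GAMMA_BOUNDS = (2.0 / 3.0, 5.0 / 3.0)
ZETA_BOUNDS = (0.5, 1.0)


@dataclass
class OpticalCalibration:
    """Sample-specific constants of the empirical g2 <-> MSD relation."""

    gamma: float
    zeta: float
    k: float  # wavenumber in the medium, rad/m (2 pi n / lambda)
    source_properties: Optional[Tuple[float, float, float]] = None  # (mus', mua, g)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("wavenumber k must be positive")
        if not GAMMA_BOUNDS[0] - 1e-9 <= self.gamma <= GAMMA_BOUNDS[1] + 1e-9:
            raise ValueError(f"gamma {self.gamma} outside DLS/DWS bounds {GAMMA_BOUNDS}")
        if not ZETA_BOUNDS[0] - 1e-9 <= self.zeta <= ZETA_BOUNDS[1] + 1e-9:
            raise ValueError(f"zeta {self.zeta} outside DLS/DWS bounds {ZETA_BOUNDS}")


def wavenumber(wavelength: float, refractive_index: float = 1.33) -> float:
    """k = 2 pi n / lambda in rad/m."""
    return 2.0 * math.pi * refractive_index / wavelength


@dataclass
class PathLengthDistribution:
    """Weighted distribution of backscattered photon path lengths.

    Path lengths ``s`` are in multiples of the transport mean free path
    l* = 1/mu_s'; ``weights`` are the detected photon weights normalized to
    unit sum.  The full exit record (all radii) is kept for reflectance and
    DRP diagnostics.
    """

    s: np.ndarray  # detected path lengths, units of l*
    weights: np.ndarray  # normalized to sum 1
    n_photons: int
    detector_radius: float  # units of l*
    scattering_orders: Optional[np.ndarray] = None
    exit_radii: Optional[np.ndarray] = None  # detected exits, units of l*
    total_reflectance: float = float("nan")  # all-radii exit weight / n_photons
    all_exit_radii: Optional[np.ndarray] = None
    all_exit_weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.s <= 0):
            raise ValueError("path lengths must be positive")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        tot = self.weights.sum()
        if abs(tot - 1.0) > 1e-12:
            raise ValueError("weights must be normalized to unit sum")

    @classmethod
    def single_scattering(cls) -> "PathLengthDistribution":
        """Degenerate distribution of single-backscattering paths (s = 2 l*),
        reproducing the DLS limit of the inversion exactly."""
        return cls(
            s=np.array([2.0]),
            weights=np.array([1.0]),
            n_photons=1,
            detector_radius=float("inf"),
            scattering_orders=np.array([1]),
        )

    def mean_scattering_order(self) -> float:
        if self.scattering_orders is None:
            return float("nan")
        return float(np.sum(self.weights * self.scattering_orders))


# ---------------------------------------------------------------------------
# random-walk photon transport (semi-infinite medium, backscatter detection)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance for a photon hitting the surface from
    inside a medium of relative index n_rel (>1 means denser medium)."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport_kernel(n_photons, g, mua_ratio, n_rel, max_path, seed):
    """Photon random walk in z >= 0; exits recorded at the z = 0 surface.

    Lengths are in units of l* = 1/mu_s'; the scattering mean free path is
    (1 - g) l*.  Absorption enters as a weight factor exp(-mua_ratio * s).
    Returns (s, weight, exit_radius, scattering_order) per exiting photon and
    the number of truncated (never-exited within max_path) photons.
    """
    np.random.seed(seed)
    s_out = np.empty(n_photons)
    w_out = np.empty(n_photons)
    r_out = np.empty(n_photons)
    o_out = np.empty(n_photons, np.int64)
    n_exit = 0
    n_trunc = 0
    mfp = 1.0 - g
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        s = 0.0
        order = 0
        exited = False
        while s < max_path:
            step = -math.log(np.random.random()) * mfp
            if uz < 0.0:
                t_hit = -z / uz
                if t_hit <= step:
                    # candidate surface crossing
                    if n_rel != 1.0:
                        refl = _fresnel_unpolarized(-uz, n_rel)
                        if np.random.random() < refl:
                            # internal reflection: fold the remainder back
                            x += ux * t_hit
                            y += uy * t_hit
                            z = 0.0
                            uz = -uz
                            s += t_hit
                            rem = step - t_hit
                            x += ux * rem
                            y += uy * rem
                            z += uz * rem
                            s += rem
                            order += 1
                            # fall through to scattering below
                            cos_t, phi_ok = _hg_and_update(g)
                            ux, uy, uz = _new_direction(ux, uy, uz, cos_t, phi_ok)
                            continue
                    x += ux * t_hit
                    y += uy * t_hit
                    s += t_hit
                    s_out[n_exit] = s
                    w_out[n_exit] = math.exp(-mua_ratio * s)
                    r_out[n_exit] = math.sqrt(x * x + y * y)
                    o_out[n_exit] = order
                    n_exit += 1
                    exited = True
                    break
            x += ux * step
            y += uy * step
            z += uz * step
            s += step
            order += 1
            cos_t, phi = _hg_and_update(g)
            ux, uy, uz = _new_direction(ux, uy, uz, cos_t, phi)
        if not exited:
            n_trunc += 1
    return s_out[:n_exit], w_out[:n_exit], r_out[:n_exit], o_out[:n_exit], n_trunc


@njit(cache=True)
def _hg_and_update(g):
    """Sample a Henyey-Greenstein deflection cosine and azimuth."""
    xi = np.random.random()
    if g > 1e-6:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
    else:
        cos_t = 2.0 * xi - 1.0
    phi = 2.0 * math.pi * np.random.random()
    return cos_t, phi


@njit(cache=True)
def _new_direction(ux, uy, uz, cos_t, phi):
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t * (1.0 if uz > 0 else -1.0)
    else:
        denom = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
        nz = -sin_t * cos_p * denom + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


def simulate_photon_paths(
    optical_properties: Tuple[float, float, float],
    detector_radius: float,
    n_photons: int,
    seed: int,
    *,
    n_rel: float = 1.0,
    max_path_lstar: float = 1e5,
) -> PathLengthDistribution:
    """Backscattered path-length distribution in a semi-infinite medium.

    Parameters
    ----------
    optical_properties : (mu_s_prime, mu_a, g) in 1/m, 1/m, dimensionless.
    detector_radius : metres; photons are detected when exiting the top
        surface within this radius of the injection point (180-degree
        backscattered configuration).  ``inf`` accepts every exit.
    n_rel : refractive index ratio medium/outside (1.0 = matched boundary).
    """
    mus_p, mua, g = optical_properties
    if mus_p <= 0:
        raise ValueError("mu_s_prime must be positive")
    if mua < 0:
        raise ValueError("mu_a must be non-negative")
    if not 0 <= g < 1:
        raise ValueError("anisotropy g must be in [0, 1)")
    if n_photons < 1e3:
        raise ValueError("n_photons must be at least 1e3")
    log_seed("simulate_photon_paths", seed)

    det_lstar = detector_radius * mus_p  # convert metres -> l* units
    mua_ratio = mua / mus_p
    # paths carrying weight < ~1e-8 contribute nothing: cap them early
    cap = max_path_lstar
    if mua_ratio > 0:
        cap = min(cap, 18.5 / mua_ratio)
    s, w, r, order, n_trunc = _transport_kernel(
        int(n_photons), float(g), float(mua_ratio), float(n_rel),
        float(cap), int(seed),
    )
    if n_trunc:
        logger.debug("simulate_photon_paths: %d photon(s) truncated", n_trunc)
    total_reflectance = float(w.sum() / n_photons)
    inside = r <= det_lstar
    if not inside.any():
        raise ValueError("no backscattered photons detected within the detector")
    wi = w[inside]
    wi = wi / wi.sum()
    return PathLengthDistribution(
        s=s[inside],
        weights=wi,
        n_photons=int(n_photons),
        detector_radius=float(det_lstar),
        scattering_orders=order[inside],
        exit_radii=r[inside],
        total_reflectance=total_reflectance,
        all_exit_radii=r,
        all_exit_weights=w,
    )


def radial_reflectance_profile(
    dist: PathLengthDistribution, r_max_lstar: float = 10.0, n_bins: int = 50
):
    """Histogram the all-exit record into a radial reflectance profile
    (weight per unit area), in l* units.  Used as a DRP oracle."""
    if dist.all_exit_radii is None:
        raise ValueError("distribution carries no full exit record")
    edges = np.linspace(0.0, r_max_lstar, n_bins + 1)
    hist, _ = np.histogram(dist.all_exit_radii, bins=edges, weights=dist.all_exit_weights)
    area = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    centres = 0.5 * (edges[1:] + edges[:-1])
    return centres, hist / (area * dist.n_photons)


# ---------------------------------------------------------------------------
# (gamma, zeta) fitting
# ---------------------------------------------------------------------------


def synthesize_dws_g2(path_dist: PathLengthDistribution, x: np.ndarray) -> np.ndarray:
    """g2 - 1 over a dimensionless ``x = k^2 <dr^2>`` grid, via the DWS
    path-integral kernel ``g1 = sum_s w(s) exp(-(x/3) (s/l*))`` and the
    Siegert relation ``g2 - 1 = g1^2``."""
    x = np.asarray(x, dtype=float)
    expo = np.outer(x / 3.0, path_dist.s)  # (nx, ns)
    g1 = np.exp(-expo) @ path_dist.weights
    return g1 * g1


def fit_g2_form(
    x: np.ndarray, g2m1: np.ndarray, fit_window: Tuple[float, float] = (0.3, 0.8)
) -> Tuple[float, float]:
    """Unclipped (gamma, zeta) of ``g2 - 1 = exp(-2 gamma x^zeta)`` by linear
    regression of ``ln(-ln(g2 - 1))`` on ``ln x`` inside the decay window."""
    x = np.asarray(x, dtype=float)
    g2m1 = np.asarray(g2m1, dtype=float)
    sel = (g2m1 > fit_window[0]) & (g2m1 < fit_window[1])
    if sel.sum() < 5:
        raise ValueError("fewer than 5 grid points inside the fit window")
    lx = np.log(x[sel])
    ly = np.log(-np.log(g2m1[sel]))
    slope, intercept = np.polyfit(lx, ly, 1)
    return float(np.exp(intercept) / 2.0), float(slope)


def fit_gamma_zeta(
    path_dist: PathLengthDistribution,
    k: float,
    msd_grid: Optional[np.ndarray] = None,
    *,
    fit_window: Tuple[float, float] = (0.3, 0.8),
    source_properties: Optional[Tuple[float, float, float]] = None,
) -> OpticalCalibration:
    """Fit (gamma, zeta) of ``g2 - 1 = exp(-2 gamma (k^2 msd)^zeta)``.

    The synthesized curve is fitted as ``ln(-ln(g2 - 1))`` linear in
    ``ln(k^2 msd)``: the slope is zeta and the intercept ln(2 gamma).  The
    fit is restricted to the central decay window of g2 - 1 (default
    0.3..0.8), the region that carries the experimental signal.  Outside it
    the stretched-exponential model degrades: toward g2 - 1 -> 1 the finite
    mean path length linearizes the decay, and toward 0 the few-step
    shortest paths dominate.
    """
    if msd_grid is None:
        x = np.logspace(-4, 1, 200)
    else:
        msd_grid = np.asarray(msd_grid, dtype=float)
        if msd_grid.max() / msd_grid.min() < 1e3:
            raise ValueError("msd_grid must span at least 3 decades")
        x = (k ** 2) * msd_grid
    g2m1 = synthesize_dws_g2(path_dist, x)
    if np.any(np.diff(g2m1) > 1e-15):
        raise ValueError("synthesized g2 curve is not monotone decreasing")
    gamma, zeta = fit_g2_form(x, g2m1, fit_window)

    tol = 1e-9  # exact-limit fits may land epsilon outside the bounds
    clipped = False
    if not GAMMA_BOUNDS[0] <= gamma <= GAMMA_BOUNDS[1]:
        clipped = abs(gamma - np.clip(gamma, *GAMMA_BOUNDS)) > tol
        gamma = float(np.clip(gamma, *GAMMA_BOUNDS))
    if not ZETA_BOUNDS[0] <= zeta <= ZETA_BOUNDS[1]:
        clipped |= abs(zeta - np.clip(zeta, *ZETA_BOUNDS)) > tol
        zeta = float(np.clip(zeta, *ZETA_BOUNDS))
    if clipped:
        warnings.warn(
            "fitted (gamma, zeta) fell outside the DLS/DWS bounds and was clipped",
            stacklevel=2,
        )
    return OpticalCalibration(
        gamma=gamma, zeta=zeta, k=k, source_properties=source_properties
    )


# ---------------------------------------------------------------------------
# lookup table
# ---------------------------------------------------------------------------

DEFAULT_MUS_GRID = tuple(np.logspace(2, 4, 5))  # 1/m, soft-tissue range
DEFAULT_MUA_GRID = tuple(np.logspace(0, 3, 4))  # 1/m
DEFAULT_G_GRID = (0.0, 0.8, 0.9)
_MUA_EPS = 1e-3


@dataclass
class GammaZetaTable:
    """Interpolable (gamma, zeta) table over a (mu_s', mu_a, g) grid.

    Queries interpolate bilinearly in (log mu_s', log(mu_a + eps)) within the
    nearest-g plane; queries outside the grid hull fall back to the nearest
    node with a warning.
    """

    mus_grid: np.ndarray
    mua_grid: np.ndarray
    g_grid: np.ndarray
    gamma: np.ndarray  # (ng, nmus, nmua)
    zeta: np.ndarray
    seed: int = 0
    n_photons: int = 0

    def query(self, mus_p: float, mua: float, g: float) -> Tuple[float, float]:
        gi = int(np.argmin(np.abs(np.asarray(self.g_grid) - g)))
        lx = math.log(mus_p)
        ly = math.log(mua + _MUA_EPS)
        gx = np.log(self.mus_grid)
        gy = np.log(self.mua_grid + _MUA_EPS)
        if not (gx[0] <= lx <= gx[-1]) or not (gy[0] <= ly <= gy[-1]):
            warnings.warn(
                "query outside the lookup grid hull; nearest-node extrapolation",
                stacklevel=2,
            )
            lx = min(max(lx, gx[0]), gx[-1])
            ly = min(max(ly, gy[0]), gy[-1])
        i = int(np.clip(np.searchsorted(gx, lx) - 1, 0, len(gx) - 2))
        j = int(np.clip(np.searchsorted(gy, ly) - 1, 0, len(gy) - 2))
        tx = (lx - gx[i]) / (gx[i + 1] - gx[i])
        ty = (ly - gy[j]) / (gy[j + 1] - gy[j])

        def interp(tab):
            p = tab[gi]
            return (
                p[i, j] * (1 - tx) * (1 - ty)
                + p[i + 1, j] * tx * (1 - ty)
                + p[i, j + 1] * (1 - tx) * ty
                + p[i + 1, j + 1] * tx * ty
            )

        return float(interp(self.gamma)), float(interp(self.zeta))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for gi, g in enumerate(self.g_grid):
            for i, mus in enumerate(self.mus_grid):
                for j, mua in enumerate(self.mua_grid):
                    rows.append(
                        (mus, mua, g, self.gamma[gi, i, j], self.zeta[gi, i, j])
                    )
        df = pd.DataFrame(rows, columns=["mu_s_prime", "mu_a", "g", "gamma", "zeta"])
        with open(path, "w") as fh:
            fh.write(f"# gamma-zeta lookup table; seed={self.seed} n_photons={self.n_photons}\n")
            df.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "GammaZetaTable":
        import pandas as pd

        seed = 0
        n_photons = 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first.split():
                    if tok.startswith("seed="):
                        seed = int(tok.split("=")[1])
                    if tok.startswith("n_photons="):
                        n_photons = int(tok.split("=")[1])
                df = pd.read_csv(fh)
            else:
                df = pd.read_csv(path)
        g_grid = np.sort(df["g"].unique())
        mus_grid = np.sort(df["mu_s_prime"].unique())
        mua_grid = np.sort(df["mu_a"].unique())
        gamma = np.empty((len(g_grid), len(mus_grid), len(mua_grid)))
        zeta = np.empty_like(gamma)
        for _, row in df.iterrows():
            gi = int(np.searchsorted(g_grid, row["g"]))
            i = int(np.searchsorted(mus_grid, row["mu_s_prime"]))
            j = int(np.searchsorted(mua_grid, row["mu_a"]))
            gamma[gi, i, j] = row["gamma"]
            zeta[gi, i, j] = row["zeta"]
        return cls(mus_grid, mua_grid, g_grid, gamma, zeta, seed, n_photons)


def build_lookup_table(
    mus_values: Sequence[float] = DEFAULT_MUS_GRID,
    mua_values: Sequence[float] = DEFAULT_MUA_GRID,
    g_values: Sequence[float] = DEFAULT_G_GRID,
    n_photons: int = 100_000,
    seed: int = 0,
    detector_radius_lstar: float = 20.0,
) -> GammaZetaTable:
    """Fit (gamma, zeta) at every grid node by Monte Carlo transport.

    Each node uses a deterministic per-node seed derived from ``seed`` so the
    whole table is reproducible.
    """
    log_seed("build_lookup_table", seed)
    mus_values = np.asarray(sorted(mus_values), dtype=float)
    mua_values = np.asarray(sorted(mua_values), dtype=float)
    g_values = np.asarray(sorted(g_values), dtype=float)
    gamma = np.empty((len(g_values), len(mus_values), len(mua_values)))
    zeta = np.empty_like(gamma)
    node = 0
    for gi, g in enumerate(g_values):
        for i, mus in enumerate(mus_values):
            for j, mua in enumerate(mua_values):
                node_seed = (seed * 1_000_003 + node) % (2 ** 31 - 1)
                node += 1
                dist = simulate_photon_paths(
                    (mus, mua, g),
                    detector_radius=detector_radius_lstar / mus,
                    n_photons=n_photons,
                    seed=node_seed,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cal = fit_gamma_zeta(dist, k=1.0)
                gamma[gi, i, j] = cal.gamma
                zeta[gi, i, j] = cal.zeta
    return GammaZetaTable(
        mus_values, mua_values, g_values, gamma, zeta, seed=seed, n_photons=n_photons
    )


# ---------------------------------------------------------------------------
# optical properties from a measured DRP
# ---------------------------------------------------------------------------


def diffusion_reflectance(rho: np.ndarray, mus_p: float, mua: float, n_rel: float = 1.0) -> np.ndarray:
    """Steady-state diffusion-approximation reflectance of a semi-infinite
    medium at radial distance rho (metres) from a pencil source."""
    rho = np.asarray(rho, dtype=float)
    mut = mus_p + mua
    z0 = 1.0 / mut
    D = 1.0 / (3.0 * mut)
    mueff = math.sqrt(3.0 * mua * mut)
    if n_rel == 1.0:
        A = 1.0
    else:
        rd = -1.44 / n_rel ** 2 + 0.71 / n_rel + 0.668 + 0.0636 * n_rel
        A = (1.0 + rd) / (1.0 - rd)
    zb = 2.0 * A * D
    r1 = np.sqrt(z0 ** 2 + rho ** 2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho ** 2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1 ** 2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2 ** 2
    return (term1 + term2) / (4.0 * math.pi)


def estimate_optical_properties(
    drp, n_rel: float = 1.0, r_min: Optional[float] = None
) -> Tuple[float, float, dict]:
    """Nonlinear least-squares fit of a radial DRP to the diffusion model.

    ``drp`` is a :class:`~shears.correlogram.DRProfile` whose
    ``radial_bins_m`` must be populated (requires pixel pitch).  Returns
    ``(mu_s_prime, mu_a, diagnostics)``.
    """
    if drp.radial_bins_m is None:
        raise ValueError("DRP has no metric radial bins (pixel pitch unknown)")
    rho = np.asarray(drp.radial_bins_m, dtype=float)
    prof = np.asarray(drp.mean_intensity, dtype=float) - drp.background
    pos = prof > 0
    # the fit needs a decaying wing; drop the innermost bins on request
    if r_min is not None:
        pos &= rho >= r_min
    if pos.sum() < 10:
        raise ValueError("need at least 10 positive radial bins to fit the DRP")
    rho_f, prof_f = rho[pos], prof[pos]
    span = prof_f.max() / prof_f.min()
    if span < 1.5:
        raise ValueError("DRP fit failed: profile is flat (no decay to fit)")

    lp = np.log(prof_f)

    def resid(theta):
        mus_p, mua, amp = np.exp(theta)
        model = diffusion_reflectance(rho_f, mus_p, mua, n_rel) * amp
        return np.log(np.maximum(model, 1e-300)) - lp

    # crude initialisation: slope of the exponential wing sets mu_eff
    x0 = np.log([1.0 / max(rho_f[np.argmax(prof_f)], rho_f[0] * 0.5 + 1e-12), 10.0, 1.0])
    x0[2] = np.log(prof_f.max() / max(
        diffusion_reflectance(rho_f, math.exp(x0[0]), 10.0, n_rel).max(), 1e-300
    ))
    lb = np.log([1e1, 1e-3, 1e-30])
    ub = np.log([1e7, 1e5, 1e30])
    sol = least_squares(resid, x0, bounds=(lb, ub), max_nfev=2000)
    if not sol.success:
        raise ValueError(f"DRP fit did not converge: {sol.message}")
    mus_p, mua, amp = np.exp(sol.x)

    # the diffusion approximation fails within ~1 transport mean free path
    # of the source: refit on the valid wing once we know where that is
    if r_min is None:
        r_cut = 0.75 / mus_p
        wing = pos & (rho >= r_cut)
        if wing.sum() >= 10 and wing.sum() < pos.sum():
            rho_f, prof_f = rho[wing], prof[wing]
            lp = np.log(prof_f)
            sol = least_squares(resid, sol.x, bounds=(lb, ub), max_nfev=2000)
            if not sol.success:
                raise ValueError(f"DRP refit did not converge: {sol.message}")
            mus_p, mua, amp = np.exp(sol.x)
            pos = wing
    at_bounds = np.any(np.isclose(sol.x, lb, atol=1e-6)) or np.any(
        np.isclose(sol.x, ub, atol=1e-6)
    )
    if at_bounds:
        raise ValueError(
            f"DRP fit hit parameter bounds (mus'={mus_p:.3g}, mua={mua:.3g})"
        )
    diag = {
        "residual": float(np.sqrt(np.mean(sol.fun ** 2))),
        "amplitude": float(amp),
        "n_points": int(pos.sum()),
    }
    return float(mus_p), float(mua), diag
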