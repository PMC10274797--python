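"""Shared fixtures: planted spectra, synthetic movies, Monte Carlo runs.

Expensive artifacts (Monte Carlo path distributions, full-chain movies) are
session-scoped so the unit suite and the acceptance suite share them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from shears.optics_calibration import (
    OpticalCalibration,
    simulate_photon_paths,
    wavenumber,
)
from shears.pipeline import process_series
from shears.rheology_core import BOLTZMANN, GSERContext
from shears.simulator import (
    InstrumentModel,
    RheoModel,
    msd_from_model,
    synthesize_speckle_movie,
    synthetic_spectrum,
)
from shears.speckle_io import SampleConfig

K637 = wavenumber(637e-9)  # 1.33 medium index


@pytest.fixture(scope="session")
def k637() -> float:
    return K637


# ---------------------------------------------------------------------------
# planted fibrin-like spectrum (regimes I, II, IIIa, IIIb)
# ---------------------------------------------------------------------------

FIBRIN_TRUTH = {
    "omega_T": 20.0,
    "omega0": 300.0,
    "G0": 700.0,
    "gamma_a": 0.4,
    "gamma_b": 1.2,
    "omega_gamma": 1.7e4,
}


def make_fibrin_spectrum(noise: float = 0.0, rng=None, points_per_decade: int = 30):
    """Planted multi-regime spectrum mirroring a fibrin-construct fingerprint."""
    n = int(points_per_decade * math.log10(3e5)) + 1
    omega = 10.0 ** (np.arange(n) / points_per_decade)
    spec, curve = synthetic_spectrum(
        omega,
        storage_anchor=(1000.0, 700.0),
        storage_slopes=[2.0, 0.0, 0.8],
        storage_breaks=[40.0, 3e4],
        loss_anchor=(300.0, 45.0),
        loss_slopes=[1.0, -0.5, 0.4, 1.2],
        loss_breaks=[15.0, 300.0, 1.7e4],
        blend_width=0.1,
    )
    if noise > 0.0:
        assert rng is not None
        spec.g_storage = spec.g_storage * rng.lognormal(0.0, noise, n)
        spec.g_loss = spec.g_loss * rng.lognormal(0.0, noise, n)
        spec.g_mag = np.hypot(spec.g_storage, spec.g_loss)
        spec.alpha = 2.0 / math.pi * np.arctan2(spec.g_loss, spec.g_storage)
        # the pipeline always smooths alpha before extraction
        from shears.rheology_core import SMOOTHING_WINDOW, _moving_average

        curve.alpha = np.clip(
            _moving_average(spec.alpha, SMOOTHING_WINDOW), 0.0, 1.0
        )
    return spec, curve


@pytest.fixture(scope="session")
def fibrin_planted():
    spec, curve = make_fibrin_spectrum()
    return spec, curve, FIBRIN_TRUTH


# ---------------------------------------------------------------------------
# Monte Carlo runs
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def diffusive_path_dist():
    """Strongly multiple-scattering backscatter run (DWS limit check)."""
    return simulate_photon_paths(
        (5000.0, 0.1, 0.0),
        detector_radius=100.0 / 5000.0,
        n_photons=100_000,
        seed=1,
    )


# ---------------------------------------------------------------------------
# full-chain Newtonian movie
# ---------------------------------------------------------------------------

NEWTONIAN_MOVIE = {
    "frame_rate": 2000.0,
    "n_frames": 8000,
    "shape": (48, 48),
    "tau_c": 0.01,  # 1/e decay time of g2 - 1, seconds
    "seed": 11,
}


def newtonian_eta_for_tau(tau_c: float, k: float = K637) -> float:
    """Viscosity giving g2 - 1 = exp(-t / tau_c) under (gamma, zeta) = (2/3, 1)."""
    d_coeff = 1.0 / (2.0 * (2.0 / 3.0) * k ** 2 * tau_c)
    return BOLTZMANN * 295.0 / (math.pi * 1.5e-6 * d_coeff)


@pytest.fixture(scope="session")
def newtonian_movie_result():
    """Movie synthesis + full pipeline for a purely viscous sample."""
    p = NEWTONIAN_MOVIE
    eta = newtonian_eta_for_tau(p["tau_c"])
    times = np.arange(1, p["n_frames"]) / p["frame_rate"]
    msd = msd_from_model(RheoModel.newtonian(eta), times)
    cal = OpticalCalibration(gamma=2.0 / 3.0, zeta=1.0, k=K637)
    inst = InstrumentModel(
        shape=p["shape"],
        frame_rate=p["frame_rate"],
        n_frames=p["n_frames"],
        seed=p["seed"],
        drp_scale=10.0,
    )
    movie = synthesize_speckle_movie(msd, cal, inst)
    result = process_series(movie, SampleConfig(gamma_zeta_override=(2.0 / 3.0, 1.0)))
    return {"eta": eta, "movie": movie, "result": result}


def loss_modulus_slope(spectrum, margin: float = 3.0):
    """Log-log slope of G'' over the interior of the valid band."""
    v = spectrum.valid & (spectrum.g_loss > 0)
    w = spectrum.omega[v]
    sel = v & (spectrum.omega > w[0] * margin) & (spectrum.omega < w[-1] / margin)
    return float(
        np.polyfit(np.log10(spectrum.omega[sel]), np.log10(spectrum.g_loss[sel]), 1)[0]
    )
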