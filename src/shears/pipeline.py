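"""End-to-end orchestration: speckle series -> spectrum -> fingerprints."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import correlogram, optics_calibration, rheology_core, spectro_params
from .optics_calibration import OpticalCalibration, wavenumber
from .rheology_core import GSERContext
from .speckle_io import RunStore, SampleConfig, SpeckleSeries

logger = logging.getLogger("shears")


@dataclass
class PipelineResult:
    drp: object
    correlation: object
    calibration: OpticalCalibration
    msd: object
    alpha: object
    spectrum: object
    params: object


def resolve_calibration(
    series: SpeckleSeries,
    sample: SampleConfig,
    drp=None,
    lookup: Optional[optics_calibration.GammaZetaTable] = None,
    n_photons: int = 50_000,
    seed: int = 0,
) -> OpticalCalibration:
    """Determine (gamma, zeta, k) for a sample.

    Priority: explicit override > lookup/Monte-Carlo from stated optical
    properties > optical properties estimated from the measured DRP.
    """
    k = wavenumber(series.wavelength, sample.refractive_index)
    if sample.gamma_zeta_override is not None:
        gam, zet = sample.gamma_zeta_override
        return OpticalCalibration(gamma=gam, zeta=zet, k=k)
    props = sample.optical_properties
    if props is None:
        if drp is None:
            raise ValueError(
                "no optical properties, override or DRP available for calibration"
            )
        mus_p, mua, _diag = optics_calibration.estimate_optical_properties(drp)
        props = (mus_p, mua, 0.0)
        logger.info(
            "estimated optical properties from DRP: mus'=%.3g 1/m mua=%.3g 1/m",
            mus_p,
            mua,
        )
    if lookup is not None:
        gam, zet = lookup.query(*props)
        return OpticalCalibration(gamma=gam, zeta=zet, k=k, source_properties=props)
    dist = optics_calibration.simulate_photon_paths(
        props, detector_radius=20.0 / props[0], n_photons=n_photons, seed=seed
    )
    cal = optics_calibration.fit_gamma_zeta(dist, k=k, source_properties=props)
    return cal


def process_series(
    series: SpeckleSeries,
    sample: SampleConfig,
    lookup: Optional[optics_calibration.GammaZetaTable] = None,
    noise_floor: float = rheology_core.DEFAULT_NOISE_FLOOR,
    store: Optional[RunStore] = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full reconstruction chain on one speckle series."""
    drp = correlogram.compute_drp(series)
    roi = correlogram.select_roi(drp, series.shape)
    if store is not None and store.has("g2"):
        corr = store.load_g2()
        logger.info("resuming: loaded g2 from run store")
    else:
        corr = correlogram.compute_g2(series, roi)
        if store is not None:
            store.save_g2(corr)
    calibration = resolve_calibration(series, sample, drp=drp, lookup=lookup, seed=seed)
    msd = rheology_core.invert_msd(corr, calibration, noise_floor=noise_floor)
    if store is not None:
        store.save_msd(msd)
    alpha = rheology_core.compute_alpha(msd)
    context = GSERContext(
        temperature=sample.temperature, particle_radius=sample.particle_radius
    )
    band = (1.0 / series.duration, series.frame_rate)
    spectrum = rheology_core.gser(alpha.resampled_msd, alpha, context, band=band)
    if store is not None:
        store.save_spectrum(spectrum)
    params = spectro_params.extract_spectro_params(spectrum, alpha)
    return PipelineResult(
        drp=drp,
        correlation=corr,
        calibration=calibration,
        msd=msd,
        alpha=alpha,
        spectrum=spectrum,
        params=params,
    )
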