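# shears

Wideband laser-speckle microrheology in Python: convert a speckle intensity
time series into frequency-dependent viscoelastic spectra G'(ω), G''(ω),
|G*(ω)| and a table of spectroscopic fingerprint parameters, with a forward
simulator that generates synthetic speckle data from prescribed viscoelastic
models so the whole chain is testable without instrument data.

## Pipeline

1. **correlogram** — locate the beam from the diffused reflectance profile
   (DRP), select a circular ROI at the 1/e radius, and compute the
   contrast-normalized intensity autocorrelation g2(t) over all ROI pixels
   and all frame pairs (exact all-pairs averages at a multi-tau lag set,
   evaluated by per-pixel FFT autocorrelation).
2. **optics_calibration** — derive the sample constants (γ, ζ) of the
   empirical inversion `g2 − 1 = exp(−2γ (k² ⟨Δr²⟩)^ζ)` by Monte Carlo
   photon transport in a semi-infinite medium (Henyey–Greenstein
   scattering, 180° backscattered detection), spanning the single-scattering
   (DLS: γ=2/3, ζ=1) to diffusive (DWS backscatter: γ=5/3, ζ=0.5) limits.
   Optical properties can be estimated from a measured radial DRP via the
   diffusion-approximation reflectance model.
3. **rheology_core** — invert g2(t) to the mean square displacement, build
   the local log-log slope α(ω) (resampling at 30 points/decade, 7-point
   rolling regression, 15-point moving average), and reconstruct
   `|G*(ω)| = k_B T / (π a Γ(1+α) ⟨Δr²(1/ω)⟩)` with
   `G' = |G*| cos(πα/2)`, `G'' = |G*| sin(πα/2)`, valid for
   1/τ < ω < F_s.
4. **spectro_params** — extract the fingerprint: fluid–solid transitions
   ω_T (α = 0.5), elastic plateaus (ω⁰, G⁰) at α minima, per-regime
   power-law exponents γ_k and α_k, the scaling-transition frequency ω_γ,
   and regime labels (I, II, IIIa, ...).
5. **simulator** — GSER-consistent MSDs for Newtonian / Maxwell /
   power-law / generalized-Maxwell / piecewise models, forward g2 curves,
   and full synthetic speckle movies (fractional-Brownian-type phasor
   dynamics, Gaussian speckle of prescribed pixels-per-speckle, DRP
   envelope, shot noise, quantization), deterministic under a seed.
6. **speckle_io** — multi-page TIFF / raw binary movies with plain-text
   sidecar metadata, CSV spectra and parameter tables, HDF5 run store for
   resumable intermediates, YAML configuration.

## CLI

```bash
# reconstruct spectra from a speckle movie
shears process --input movie.tif --meta movie.tif.meta.yaml \
               --config sample.yaml --out results/

# generate a synthetic movie from a viscoelastic model
shears simulate --model model.yaml --instrument instrument.yaml \
                --out simdir/ --seed 1

# fit (gamma, zeta) for given optical properties by Monte Carlo
shears calibrate --mu-s 1000 --mu-a 10 --g 0.9 --n-photons 100000 --seed 1
```

`sample.yaml` example:

```yaml
refractive_index: 1.33
temperature: 295.0
particle_radius: 1.5e-6
optical_properties: {mu_s_prime: 1000.0, mu_a: 10.0, g: 0.9}
# or pin the inversion constants directly:
# gamma_zeta_override: {gamma: 1.2, zeta: 0.7}
```

`model.yaml` example:

```yaml
kind: maxwell
params: {g0: 700.0, tau: 0.05}
temperature: 295.0
particle_radius: 1.5e-6
```

## Python API sketch

```python
import numpy as np
import shears

series = shears.read_speckle_series("movie.tif")
sample = shears.SampleConfig(gamma_zeta_override=(5 / 3, 0.5))
result = shears.process_series(series, sample)
shears.write_results(result.spectrum, result.params, "out/")
```
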