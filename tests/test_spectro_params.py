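import math

import numpy as np
import pytest

from conftest import FIBRIN_TRUTH, make_fibrin_spectrum
from shears.rheology_core import AlphaCurve, ViscoSpectrum
from shears.simulator import synthetic_spectrum
from shears.spectro_params import (
    Plateau,
    ScalingTransition,
    Transition,
    extract_spectro_params,
    find_plateaus,
    find_scaling_transition,
    find_transitions,
    fit_power_laws,
    segment_regimes,
)


def alpha_curve(omega, alpha):
    alpha = np.asarray(alpha, dtype=float)
    return AlphaCurve(
        omega=np.asarray(omega, dtype=float),
        alpha=alpha,
        alpha_raw=alpha.copy(),
        msd=np.ones(len(alpha)),
        low_confidence=np.zeros(len(alpha), bool),
    )


def power_spectrum(omega, g_storage, g_loss):
    g_storage = np.asarray(g_storage, float)
    g_loss = np.asarray(g_loss, float)
    mag = np.hypot(g_storage, g_loss)
    return ViscoSpectrum(
        omega=np.asarray(omega, float),
        g_storage=g_storage,
        g_loss=g_loss,
        g_mag=mag,
        alpha=2.0 / math.pi * np.arctan2(g_loss, g_storage),
        valid=np.ones(len(g_loss), bool),
    )


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


class TestFindTransitions:
    def test_crossing_interpolated_at_log_midpoint(self):
        omega = np.array([10.0, 100.0, 1000.0])
        curve = alpha_curve(omega, [0.8, 0.6, 0.4])
        out = find_transitions(curve)
        assert len(out) == 1
        # 0.6 -> 0.4 crossing: halfway in log omega between 100 and 1000
        assert out[0].omega == pytest.approx(10 ** 2.5, rel=1e-9)
        assert out[0].direction == "fluid->solid"

    def test_rising_crossing_direction(self):
        omega = np.logspace(0, 2, 5)
        curve = alpha_curve(omega, [0.2, 0.3, 0.45, 0.55, 0.7])
        out = find_transitions(curve)
        assert len(out) == 1
        assert out[0].direction == "solid->fluid"

    def test_no_crossing_gives_empty_list(self):
        omega = np.logspace(0, 2, 10)
        curve = alpha_curve(omega, np.full(10, 0.8))
        assert find_transitions(curve) == []

    def test_maxwell_crossover_at_inverse_relaxation_time(self):
        """Maxwell model, tau = 0.05 s: alpha = 0.5 at omega = 20 rad/s."""
        from shears.rheology_core import compute_alpha
        from shears.simulator import RheoModel, msd_from_model

        tau = 0.05
        model = RheoModel.maxwell(g0=2.0, tau=tau)
        times = np.logspace(-4, 1, 300)
        ac = compute_alpha(msd_from_model(model, times))
        out = find_transitions(ac)
        assert len(out) == 1
        assert out[0].omega == pytest.approx(1.0 / tau, rel=0.10)
        # alpha falls from 1 (low omega, fluid) toward 0 (high omega, solid)
        assert out[0].direction == "fluid->solid"


# ---------------------------------------------------------------------------
# plateaus
# ---------------------------------------------------------------------------


class TestFindPlateaus:
    def test_monotone_alpha_gives_no_plateau(self):
        omega = np.logspace(0, 3, 40)
        curve = alpha_curve(omega, np.linspace(1.0, 0.1, 40))
        spec = power_spectrum(omega, np.ones(40), np.ones(40))
        assert find_plateaus(spec, curve) == []

    def test_single_planted_minimum_recovered(self):
        omega = np.logspace(0, 4, 121)
        x = np.log10(omega)
        alpha = 0.5 + 0.4 * (x - 2.0) ** 2 / 4.0  # parabola, min at omega = 100
        alpha = np.clip(alpha, 0, 1)
        curve = alpha_curve(omega, alpha)
        gp = np.full(121, 50.0)
        spec = power_spectrum(omega, gp, gp * np.tan(math.pi * alpha / 2))
        out = find_plateaus(spec, curve)
        assert len(out) == 1
        assert out[0].omega == pytest.approx(100.0, rel=0.05)
        assert out[0].modulus == pytest.approx(50.0, rel=1e-9)

    def test_shallow_minimum_below_prominence_ignored(self):
        omega = np.logspace(0, 4, 121)
        x = np.log10(omega)
        alpha = 0.5 + 0.01 * (x - 2.0) ** 2  # only 0.04 deep
        curve = alpha_curve(omega, alpha)
        spec = power_spectrum(omega, np.ones(121), np.ones(121))
        assert find_plateaus(spec, curve, prominence=0.05) == []

    def test_fibrin_plateau_within_fifteen_percent(self, fibrin_planted):
        spec, curve, truth = fibrin_planted
        out = find_plateaus(spec, curve)
        assert len(out) == 1
        assert out[0].omega == pytest.approx(truth["omega0"], rel=0.15)
        assert out[0].modulus == pytest.approx(truth["G0"], rel=0.15)


# ---------------------------------------------------------------------------
# power-law fits
# ---------------------------------------------------------------------------


class TestFitPowerLaws:
    def test_exact_power_law_recovered_with_zero_stderr(self):
        omega = np.logspace(1, 3, 61)
        spec = power_spectrum(omega, 5.0 * omega ** 0.1, 2.0 * omega ** 0.4)
        gfits, afits = fit_power_laws(spec, [(omega[0], omega[-1])])
        assert gfits[0].exponent == pytest.approx(0.4, abs=1e-12)
        assert gfits[0].stderr == pytest.approx(0.0, abs=1e-10)

    def test_newtonian_loss_slope_is_one(self):
        omega = np.logspace(0, 3, 91)
        spec = power_spectrum(omega, np.full(91, 1e-12), 1.4e-3 * omega)
        gfits, _ = fit_power_laws(spec, [(omega[0], omega[-1])])
        assert gfits[0].exponent == pytest.approx(1.0, abs=1e-6)

    def test_two_segment_fit_recovers_both_exponents(self):
        omega = np.logspace(0, 5, 151)
        b = 1.7e4
        gl = np.where(omega <= b, 2.0 * omega ** 0.4, 2.0 * b ** (0.4 - 1.2) * omega ** 1.2)
        spec = power_spectrum(omega, np.full(151, 1.0), gl)
        gfits, _ = fit_power_laws(spec, [(1.0, b), (b, 1e5)])
        assert gfits[0].exponent == pytest.approx(0.4, abs=0.05)
        assert gfits[1].exponent == pytest.approx(1.2, abs=0.05)

    def test_non_positive_values_rejected(self):
        omega = np.logspace(0, 2, 31)
        spec = power_spectrum(omega, np.ones(31), np.ones(31))
        spec.g_loss[5] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_power_laws(spec, [(omega[0], omega[-1])])

    def test_short_interval_rejected(self):
        omega = np.logspace(0, 2, 31)
        spec = power_spectrum(omega, np.ones(31), omega)
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_power_laws(spec, [(50.0, 60.0)])


# ---------------------------------------------------------------------------
# scaling transition
# ---------------------------------------------------------------------------


def blended_loss_spectrum(omega, slopes, breaks, width=0.1):
    spec, _ = synthetic_spectrum(
        omega,
        storage_anchor=(100.0, 1.0),
        storage_slopes=[0.0],
        storage_breaks=[],
        loss_anchor=(breaks[0] if breaks else 100.0, 10.0),
        loss_slopes=slopes,
        loss_breaks=breaks,
        blend_width=width,
    )
    return spec


class TestFindScalingTransition:
    def test_planted_break_located(self):
        omega = np.logspace(2, 6, 121)
        spec = blended_loss_spectrum(omega, [0.4, 1.2], [1.7e4])
        st = find_scaling_transition(spec, (1e2, 1e6))
        assert st.multiplicity == 1
        assert st.omega is not None
        assert abs(math.log10(st.omega / 1.7e4)) < math.log10(1.3)

    def test_pure_power_law_absent(self):
        omega = np.logspace(2, 6, 121)
        spec = power_spectrum(omega, np.ones(121), 0.3 * omega ** 0.7)
        st = find_scaling_transition(spec, (1e2, 1e6))
        assert st.omega is None
        assert st.multiplicity == 0

    def test_three_exponent_segment_reports_multiplicity_two(self):
        omega = np.logspace(1, 7, 181)
        spec = blended_loss_spectrum(omega, [0.2, 0.7, 1.2], [1e3, 1e5])
        st = find_scaling_transition(spec, (1e1, 1e7))
        assert st.omega is None
        assert st.multiplicity == 2


# ---------------------------------------------------------------------------
# regimes
# ---------------------------------------------------------------------------


class TestSegmentRegimes:
    def test_featureless_spectrum_is_single_regime(self):
        omega = np.logspace(0, 4, 121)
        curve = alpha_curve(omega, np.full(121, 0.7))
        regimes = segment_regimes(curve, [], [], [])
        assert [r.label for r in regimes] == ["I"]
        assert regimes[0].omega_lo == omega[0]
        assert regimes[0].omega_hi == omega[-1]

    def test_fibrin_labels_in_order(self, fibrin_planted):
        spec, curve, _ = fibrin_planted
        params = extract_spectro_params(spec, curve)
        assert [r.label for r in params.regimes] == ["I", "II", "IIIa", "IIIb"]
        # regime intervals ordered, non-overlapping, covering the band
        los = [r.omega_lo for r in params.regimes]
        his = [r.omega_hi for r in params.regimes]
        assert los == sorted(los)
        for hi, lo_next in zip(his[:-1], los[1:]):
            assert hi == pytest.approx(lo_next, rel=1e-12)

    def test_two_plateaus_two_scalings_labelled_to_five(self):
        omega = np.logspace(0, 6, 181)
        curve = alpha_curve(omega, np.full(181, 0.4))
        transitions = [Transition(omega=3.0, direction="fluid->solid")]
        plateaus = [
            Plateau(omega=100.0, modulus=10.0, alpha_min=0.1),
            Plateau(omega=1e4, modulus=30.0, alpha_min=0.15),
        ]
        regimes = segment_regimes(curve, transitions, plateaus, [])
        assert [r.label for r in regimes] == ["I", "II", "III", "IV", "V"]
        kinds = [r.kind for r in regimes]
        assert kinds == ["initial", "plateau", "scaling", "plateau", "scaling"]

    def test_scaling_split_into_sub_labels(self):
        omega = np.logspace(0, 6, 181)
        curve = alpha_curve(omega, np.full(181, 0.4))
        plateaus = [Plateau(omega=100.0, modulus=10.0, alpha_min=0.1)]
        splits = [ScalingTransition(omega=1e4, multiplicity=1)]
        regimes = segment_regimes(curve, [], plateaus, splits)
        assert [r.label for r in regimes] == ["I", "II", "IIIa", "IIIb"]


# ---------------------------------------------------------------------------
# whole-table extraction
# ---------------------------------------------------------------------------


class TestExtraction:
    def test_fibrin_fingerprint_recovered(self, fibrin_planted):
        spec, curve, truth = fibrin_planted
        p = extract_spectro_params(spec, curve)
        assert p.transitions[0].omega == pytest.approx(truth["omega_T"], rel=0.15)
        assert p.plateaus[0].omega == pytest.approx(truth["omega0"], rel=0.15)
        assert p.plateaus[0].modulus == pytest.approx(truth["G0"], rel=0.15)
        gammas = {f.label: f.exponent for f in p.loss_exponents}
        assert gammas["IIIa"] == pytest.approx(truth["gamma_a"], rel=0.15)
        assert gammas["IIIb"] == pytest.approx(truth["gamma_b"], rel=0.15)
        st = [s for s in p.scaling_transitions if s.omega is not None]
        assert len(st) == 1
        assert abs(math.log10(st[0].omega / truth["omega_gamma"])) < math.log10(1.3)

    def test_rescaling_moduli_scales_only_plateau_modulus(self, fibrin_planted):
        spec, curve, _ = fibrin_planted
        p1 = extract_spectro_params(spec, curve)
        scaled = ViscoSpectrum(
            omega=spec.omega,
            g_storage=spec.g_storage * 37.0,
            g_loss=spec.g_loss * 37.0,
            g_mag=spec.g_mag * 37.0,
            alpha=spec.alpha,
            valid=spec.valid,
        )
        p2 = extract_spectro_params(scaled, curve)
        assert p2.plateaus[0].modulus == pytest.approx(
            37.0 * p1.plateaus[0].modulus, rel=1e-9
        )
        assert p2.transitions[0].omega == pytest.approx(p1.transitions[0].omega, rel=1e-9)
        assert p2.plateaus[0].omega == pytest.approx(p1.plateaus[0].omega, rel=1e-9)
        for f1, f2 in zip(p1.loss_exponents, p2.loss_exponents):
            assert f2.exponent == pytest.approx(f1.exponent, abs=1e-9)

    def test_grid_resolution_stability_at_60_per_decade(self):
        spec30, curve30 = make_fibrin_spectrum(points_per_decade=30)
        spec60, curve60 = make_fibrin_spectrum(points_per_decade=60)
        p30 = extract_spectro_params(spec30, curve30)
        p60 = extract_spectro_params(spec60, curve60)
        step30 = math.log10(spec30.omega[1] / spec30.omega[0])
        for a, b in [
            (p30.transitions[0].omega, p60.transitions[0].omega),
            (p30.plateaus[0].omega, p60.plateaus[0].omega),
        ]:
            assert abs(math.log10(b / a)) <= step30

    def test_planted_recovery_under_noise_median_within_fifteen_percent(self):
        """100 random multi-regime spectra with 5% multiplicative noise."""
        rng = np.random.default_rng(1234)
        errors = {k: [] for k in ("omega_T", "omega0", "G0", "gamma_a", "gamma_b", "omega_gamma")}
        n_trials = 100
        for _ in range(n_trials):
            truth = {
                "omega_T": 10 ** rng.uniform(0.9, 1.6),
                "omega0": 10 ** rng.uniform(2.2, 2.8),
                "G0": 10 ** rng.uniform(1.5, 3.5),
                "gamma_a": rng.uniform(0.25, 0.5),
                "gamma_b": rng.uniform(0.9, 1.3),
                "omega_gamma": 10 ** rng.uniform(4.0, 4.5),
            }
            n = int(30 * math.log10(3e5)) + 1
            omega = 10.0 ** (np.arange(n) / 30)
            g_min_ratio = rng.uniform(0.05, 0.08)
            spec, curve = synthetic_spectrum(
                omega,
                storage_anchor=(1000.0, truth["G0"]),
                storage_slopes=[2.0, 0.0, 0.8],
                storage_breaks=[2.0 * truth["omega_T"], 3e4],
                loss_anchor=(truth["omega0"], g_min_ratio * truth["G0"]),
                loss_slopes=[1.0, -0.5, truth["gamma_a"], truth["gamma_b"]],
                loss_breaks=[
                    0.75 * truth["omega_T"],
                    truth["omega0"],
                    truth["omega_gamma"],
                ],
                blend_width=0.1,
            )
            spec.g_storage = spec.g_storage * rng.lognormal(0, 0.05, n)
            spec.g_loss = spec.g_loss * rng.lognormal(0, 0.05, n)
            spec.g_mag = np.hypot(spec.g_storage, spec.g_loss)
            spec.alpha = 2 / math.pi * np.arctan2(spec.g_loss, spec.g_storage)
            from shears.rheology_core import SMOOTHING_WINDOW, _moving_average

            curve.alpha = np.clip(
                _moving_average(spec.alpha, SMOOTHING_WINDOW), 0.0, 1.0
            )
            p = extract_spectro_params(spec, curve)
            if p.transitions:
                errors["omega_T"].append(
                    abs(p.transitions[0].omega - truth["omega_T"]) / truth["omega_T"]
                )
            if p.plateaus:
                errors["omega0"].append(
                    abs(p.plateaus[0].omega - truth["omega0"]) / truth["omega0"]
                )
                errors["G0"].append(
                    abs(p.plateaus[0].modulus - truth["G0"]) / truth["G0"]
                )
            gammas = {f.label: f.exponent for f in p.loss_exponents}
            if "IIIa" in gammas:
                errors["gamma_a"].append(
                    abs(gammas["IIIa"] - truth["gamma_a"]) / truth["gamma_a"]
                )
            if "IIIb" in gammas:
                errors["gamma_b"].append(
                    abs(gammas["IIIb"] - truth["gamma_b"]) / truth["gamma_b"]
                )
            found = [s for s in p.scaling_transitions if s.omega is not None]
            if found:
                errors["omega_gamma"].append(
                    abs(found[0].omega - truth["omega_gamma"]) / truth["omega_gamma"]
                )
        for name, errs in errors.items():
            assert len(errs) >= n_trials // 2, f"{name} recovered in too few trials"
            assert np.median(errs) <= 0.15, f"{name} median err {np.median(errs):.3f}"
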