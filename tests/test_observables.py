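"""Observable models, synthetic experiments and the fitting chain."""

import numpy as np
import pytest

from hingekit.kinetics import (
    RateConstants,
    derive_equilibrium,
    lock_state,
    pre_equilibrium_kon,
)
from hingekit.observables import (
    DistanceDistribution,
    FitError,
    FretParams,
    KineticTrace,
    TitrationCurve,
    bound_fraction_quadratic,
    decompose_deer,
    deer_distribution,
    fit_exponential,
    fit_isotherm,
    fit_pseudo_first_order,
    fret_efficiency,
    fret_signal,
    infer_fy_from_kon_ratio,
    simulate_association,
    simulate_titration,
)


class TestFret:
    def test_efficiency_half_at_r0(self):
        assert fret_efficiency(51.0, 51.0) == pytest.approx(0.5)

    def test_efficiency_limits(self):
        assert fret_efficiency(1e-6, 51.0) == pytest.approx(1.0)
        assert fret_efficiency(102.0, 51.0) == pytest.approx(1.0 / 65.0)

    def test_signal_increases_when_population_shifts_to_y(self):
        params = FretParams(r0=51.0, d_state={"X": 60.0, "Y": 40.0})
        s_x = fret_signal({"X": 1.0, "Y": 0.0, "YP": 0.0}, params)
        s_yp = fret_signal({"X": 0.0, "Y": 0.0, "YP": 1.0}, params)
        assert s_yp > s_x
        assert s_x < params.background + 0.5 * params.scale

    def test_degenerate_distances_make_signal_population_independent(self):
        params = FretParams(d_state={"X": 50.0, "Y": 50.0})
        a = fret_signal({"X": 0.5, "Y": 0.5, "YP": 0.0}, params)
        b = fret_signal({"X": 0.1, "Y": 0.2, "YP": 0.7}, params)
        assert a == pytest.approx(b)

    def test_missing_state_distance_is_error(self):
        with pytest.raises(ValueError, match="distance"):
            fret_signal({"X": 1.0}, FretParams(d_state={"Y": 40.0}))


class TestBoundFraction:
    def test_no_ligand_zero(self):
        assert bound_fraction_quadratic(1e-9, 1e-6, 0.0) == 0.0

    def test_saturation(self):
        assert bound_fraction_quadratic(1e-9, 1e-3, 1e-9) == pytest.approx(
            1.0, rel=1e-4)

    def test_half_saturation_limit(self):
        kd = 1e-6
        frac = bound_fraction_quadratic(kd, kd, 1e-15)
        assert frac == pytest.approx(0.5, rel=1e-6)

    def test_stable_in_tight_binding_regime(self):
        # kd << totals: naive quadratic root would cancel catastrophically
        frac = bound_fraction_quadratic(1e-15, 1e-6, 1e-6)
        assert 0.99 < frac <= 1.0


class TestSimulators:
    def test_titration_reproducible_for_fixed_seed(self, base_rates):
        series = np.geomspace(1e-8, 1e-4, 10)
        a = simulate_titration(base_rates, 1e-9, series, "fp", 0.01, seed=7)
        b = simulate_titration(base_rates, 1e-9, series, "fp", 0.01, seed=7)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_off_target_titration_is_flat(self, base_rates):
        """A partner whose apparent K_D is 1000x the top concentration
        produces < 1% of the on-target amplitude."""
        series = np.geomspace(1e-8, 1e-5, 10)
        on = simulate_titration(base_rates, 1e-9, series, "fp")
        eq = derive_equilibrium(base_rates)
        # same intrinsic chemistry, but conformational balance pushed so far
        # toward X that K_D,app = 1000 x the top concentration
        kd_target = 1000.0 * series[-1]
        f_y_off = eq.kd_intrinsic / kd_target
        off_rates = RateConstants(f_y_off * 2000.0, (1 - f_y_off) * 2000.0,
                                  base_rates.k2, base_rates.k_m2)
        off = simulate_titration(off_rates, 1e-9, series, "fp")
        on_amp = on.signal.max() - on.signal.min()
        off_amp = off.signal.max() - off.signal.min()
        assert off_amp < 0.01 * on_amp

    def test_association_pseudo_first_order_warning(self, base_rates):
        traces = simulate_association(base_rates, 1e-7,
                                      np.array([2e-7, 1e-5]), "fp")
        assert traces[0].meta["pseudo_first_order_warning"]
        assert not traces[1].meta["pseudo_first_order_warning"]

    def test_association_reproducible(self, base_rates):
        t = np.linspace(0, 100, 50)
        a = simulate_association(base_rates, 2e-9, np.array([1e-6]), "fp",
                                 t, noise_sd=0.02, seed=3)[0]
        b = simulate_association(base_rates, 2e-9, np.array([1e-6]), "fp",
                                 t, noise_sd=0.02, seed=3)[0]
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_noise_free_separated_trace_is_single_exponential(self, base_rates):
        # probe low enough that ligand depletion cannot curve the trace
        trace = simulate_association(base_rates, 2e-12, np.array([1e-6]),
                                     "fp")[0]
        fit = fit_exponential(trace)
        amp = abs(fit.params["amplitude"])
        assert fit.residual_rms < 1e-6 * amp


class TestFitExponential:
    def test_noise_free_round_trip(self):
        t = np.linspace(0.0, 60.0, 120)
        y = 0.2 + 0.8 * (1 - np.exp(-0.1 * t))
        fit = fit_exponential(KineticTrace(t, y))
        assert fit.converged
        assert fit.params["k_app"] == pytest.approx(0.1, rel=1e-6)
        assert fit.params["amplitude"] == pytest.approx(0.8, rel=1e-6)

    def test_constant_signal_flagged(self):
        t = np.linspace(0.0, 10.0, 20)
        fit = fit_exponential(KineticTrace(t, np.full_like(t, 0.3)))
        assert fit.params["amplitude"] == pytest.approx(0.0, abs=1e-9)
        assert "unidentifiable" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_exponential(KineticTrace(np.arange(5.0), np.arange(5.0)))

    def test_noisy_replicates_recover_rate(self, rng):
        """Median fitted rate over noisy replicates within 1% of truth
        (2% amplitude noise)."""
        t = np.linspace(0.0, 50.0, 100)
        truth = 0.1
        clean = 1.0 * (1 - np.exp(-truth * t))
        fits = []
        for _ in range(300):
            y = clean + rng.normal(0.0, 0.02, t.shape)
            fits.append(fit_exponential(KineticTrace(t, y)).params["k_app"])
        assert np.median(fits) == pytest.approx(truth, rel=0.01)


class TestFitPseudoFirstOrder:
    def test_exact_line_recovered(self):
        concs = np.array([0.2, 0.4, 0.6, 0.8, 1.0]) * 1e-6
        k_apps = 7.8e4 * concs + 0.05
        fit = fit_pseudo_first_order(k_apps, concs)
        assert fit.params["k_on"] == pytest.approx(7.8e4, rel=1e-9)
        assert fit.params["k_off"] == pytest.approx(0.05, rel=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(FitError):
            fit_pseudo_first_order([0.1, 0.2], [1e-6, 2e-6])

    def test_weighting_prefers_precise_points(self):
        concs = np.array([1.0, 2.0, 3.0, 4.0]) * 1e-6
        k_apps = np.array([0.1, 0.2, 0.3, 10.0])  # last point corrupted
        se = np.array([1e-3, 1e-3, 1e-3, 1e3])    # ... and known-noisy
        fit = fit_pseudo_first_order(k_apps, concs, se)
        assert fit.params["k_on"] == pytest.approx(1e5, rel=1e-3)


class TestFitIsotherm:
    def test_quadratic_round_trip(self, base_rates):
        eq = derive_equilibrium(base_rates)
        series = np.geomspace(1e-8, 1e-4, 12)
        curve = simulate_titration(base_rates, 1e-9, series, "fp")
        fit = fit_isotherm(curve, "quadratic")
        assert fit.params["kd"] == pytest.approx(eq.kd_app, rel=1e-4)

    def test_hyperbolic_biased_under_depletion(self):
        """Probe at 10x K_D: the hyperbolic model overestimates K_D by >20%
        where the depletion-exact quadratic stays within 1%."""
        kd = 1e-9
        probe = 10 * kd
        series = np.geomspace(1e-10, 1e-6, 14)
        from hingekit.observables import _bound_conc
        signal = np.array([_bound_conc(kd, c, probe) / probe for c in series])
        curve = TitrationCurve(series, signal, {"probe_tot": probe})
        quad = fit_isotherm(curve, "quadratic")
        hyp = fit_isotherm(curve, "hyperbolic")
        assert abs(quad.params["kd"] / kd - 1) < 0.01
        assert abs(hyp.params["kd"] / kd - 1) > 0.20

    def test_flat_curve_flagged(self):
        series = np.geomspace(1e-9, 1e-5, 8)
        curve = TitrationCurve(series, np.full(8, 0.5), {"probe_tot": 1e-9})
        fit = fit_isotherm(curve)
        assert "unidentifiable" in fit.flags


class TestDeer:
    def test_single_state_unimodal_normalized(self):
        d = deer_distribution([1.0], [45.0])
        assert d.r[np.argmax(d.density)] == pytest.approx(45.0, abs=0.5)
        assert np.trapezoid(d.density, d.r) == pytest.approx(1.0, abs=1e-6)
        assert not d.truncated

    def test_two_state_bimodal(self):
        d = deer_distribution([0.3, 0.7], [45.0, 32.0])
        for mean in (45.0, 32.0):
            i = np.argmin(np.abs(d.r - mean))
            assert d.density[i] > d.density[i - 6]
            assert d.density[i] > d.density[i + 6]

    def test_truncated_tail_renormalized_and_flagged(self):
        d = deer_distribution([1.0], [79.0])
        assert d.truncated
        assert np.trapezoid(d.density, d.r) == pytest.approx(1.0, abs=1e-6)

    def test_decompose_round_trip(self):
        bx = deer_distribution([1.0], [45.0])
        by = deer_distribution([1.0], [32.0])
        obs = DistanceDistribution(bx.r, 0.3 * bx.density + 0.7 * by.density)
        fit = decompose_deer(obs, bx, by)
        assert fit.params["w_x"] == pytest.approx(0.3, abs=1e-6)
        assert fit.params["w_y"] == pytest.approx(0.7, abs=1e-6)

    def test_pure_state(self):
        bx = deer_distribution([1.0], [45.0])
        by = deer_distribution([1.0], [32.0])
        fit = decompose_deer(bx, bx, by)
        assert fit.params["w_x"] == pytest.approx(1.0, abs=1e-9)

    def test_collinear_bases_flagged(self):
        bx = deer_distribution([1.0], [45.0])
        by = deer_distribution([1.0], [45.2])
        fit = decompose_deer(bx, bx, by)
        assert "unidentifiable" in fit.flags

    def test_noisy_weight_recovery_rmse(self, rng):
        """1% density noise, 200 replicates: weight RMSE < 0.02."""
        bx = deer_distribution([1.0], [45.0])
        by = deer_distribution([1.0], [32.0])
        errors = []
        for _ in range(200):
            w = rng.uniform(0.1, 0.9)
            clean = w * bx.density + (1 - w) * by.density
            noisy = clean + rng.normal(0.0, 0.01 * clean.max(), clean.shape)
            obs = DistanceDistribution(bx.r, np.clip(noisy, 0.0, None))
            fit = decompose_deer(obs, bx, by)
            errors.append(fit.params["w_x"] - w)
        assert np.sqrt(np.mean(np.square(errors))) < 0.02


class TestInferFy:
    def test_200_fold_ratio_gives_half_percent(self):
        f_y, flags = infer_fy_from_kon_ratio(1.0, 200.0, f_y_reference=1.0)
        assert f_y == pytest.approx(0.005)
        assert "assumes_identical_k2" in flags

    def test_equal_rates_identity(self):
        f_y, _ = infer_fy_from_kon_ratio(5.0, 5.0, 0.3)
        assert f_y == pytest.approx(0.3)

    def test_22_fold_occupancy_increase(self):
        f_ref = 0.005
        f_y, _ = infer_fy_from_kon_ratio(22.0, 1.0, f_ref)
        assert f_y / f_ref == pytest.approx(22.0)

    def test_inconsistent_ratio_clipped(self):
        f_y, flags = infer_fy_from_kon_ratio(10.0, 1.0, 0.5)
        assert f_y == 1.0
        assert "inconsistent_ratio" in flags


class TestEndToEndIdentifiability:
    def test_kon_recovery_over_random_rate_sets(self, rng):
        """simulate -> exponential fits -> slope regression recovers
        k2 * F_Y within 2% (noise-free) for rate sets with timescale
        separation >= 100."""
        concs = np.array([0.2, 0.4, 0.6, 0.8, 1.0]) * 1e-6
        for _ in range(15):
            f_y = 10.0 ** rng.uniform(-3, -1)
            k_sum = 10.0 ** rng.uniform(3, 4.5)
            k2 = 10.0 ** rng.uniform(5, 6)
            k_m2 = 10.0 ** rng.uniform(-2.5, -1.5)
            if k_sum < 100.0 * (k2 * concs[-1] + k_m2):
                continue
            rates = RateConstants(f_y * k_sum, (1 - f_y) * k_sum, k2, k_m2)
            traces = simulate_association(rates, 2e-9, concs, "fp")
            ks = [fit_exponential(t).params["k_app"] for t in traces]
            fit = fit_pseudo_first_order(ks, concs)
            assert fit.params["k_on"] == pytest.approx(k2 * f_y, rel=0.02)

    def test_kon_recovery_with_noise(self, base_rates):
        """Noise at 2% of each trace's amplitude: recovered slope within
        10% of k2 * F_Y (exponential-fit standard errors as weights)."""
        concs = np.array([0.2, 0.4, 0.6, 0.8, 1.0]) * 1e-6
        clean = simulate_association(base_rates, 2e-9, concs, "fp")
        ks, ses = [], []
        for i, (conc, ref) in enumerate(zip(concs, clean)):
            span = ref.signal.max() - ref.signal.min()
            trace = simulate_association(base_rates, 2e-9, np.array([conc]),
                                         "fp", noise_sd=0.02 * span,
                                         seed=11 + i)[0]
            fit = fit_exponential(trace)
            ks.append(fit.params["k_app"])
            ses.append(fit.se["k_app"])
        fit = fit_pseudo_first_order(ks, concs, ses)
        truth = pre_equilibrium_kon(base_rates)[0]
        assert fit.params["k_on"] == pytest.approx(truth, rel=0.10)

    def test_titration_kd_app_equals_intrinsic_over_fy(self, base_rates):
        """Coupling of the equilibria: fitted K_D of a simulated titration
        equals K_D,intrinsic / F_Y within 1%."""
        eq = derive_equilibrium(base_rates)
        series = np.geomspace(1e-8, 1e-4, 12)
        curve = simulate_titration(base_rates, 1e-9, series, "fp")
        fit = fit_isotherm(curve, "quadratic")
        assert fit.params["kd"] == pytest.approx(
            eq.kd_intrinsic / eq.f_y, rel=0.01)
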