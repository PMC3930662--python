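"""Combination index, Fa-CI profiles, classification and design helpers."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from combindex import (
    CI_SCALE,
    AgentSpec,
    CombinationMeasurement,
    ConstantRatioDesign,
    DomainError,
    InteractionSpec,
    MedianEffectModel,
    PlateConfig,
    UndefinedCIError,
    aggregate,
    ci_at_design_point,
    classify_ci,
    combination_index,
    design_dose_series,
    dose_for_fa,
    fa_ci_curve,
    fit_mixture,
    generate_study,
    metal_complex_ratio,
    predict_fa,
    run_study,
)
from conftest import noise_free_dataset


class TestCombinationIndex:
    def test_half_median_doses_are_additive(self):
        ma = MedianEffectModel(dm=10, m=1)
        mb = MedianEffectModel(dm=20, m=1)
        res = combination_index(
            CombinationMeasurement(dose_a=5, dose_b=10, fa_observed=0.5),
            ma, mb)
        assert res.ci == pytest.approx(1.0, abs=1e-12)
        assert res.dxa == pytest.approx(10)
        assert res.dxb == pytest.approx(20)

    @pytest.mark.parametrize("split", [0.5, 0.2, 0.9])
    def test_sham_self_combination_is_additive(self, split):
        """A drug combined with itself is Loewe-additive at any split."""
        model = MedianEffectModel(dm=3.7, m=1.8)
        for total in [0.5, 3.7, 12.0]:
            fa = predict_fa(model, total)
            res = combination_index(
                CombinationMeasurement(dose_a=split * total,
                                       dose_b=(1 - split) * total,
                                       fa_observed=fa),
                model, model)
            assert res.ci == pytest.approx(1.0, abs=1e-9)

    def test_fa_extremes_undefined(self):
        m = MedianEffectModel(dm=1, m=1)
        for fa in (0.0, 1.0):
            with pytest.raises((UndefinedCIError, DomainError)):
                combination_index(
                    CombinationMeasurement(dose_a=1, dose_b=1,
                                           fa_observed=fa), m, m)

    def test_scale_invariance(self):
        """Rescaling both drugs' dose units leaves CI unchanged."""
        ma, mb = MedianEffectModel(dm=2, m=1.5), MedianEffectModel(dm=8, m=2.5)
        res1 = combination_index(
            CombinationMeasurement(1.0, 3.0, 0.4), ma, mb)
        c = 1000.0
        ma2 = MedianEffectModel(dm=2 * c, m=1.5)
        mb2 = MedianEffectModel(dm=8 * c, m=2.5)
        res2 = combination_index(
            CombinationMeasurement(1.0 * c, 3.0 * c, 0.4), ma2, mb2)
        assert res2.ci == pytest.approx(res1.ci, rel=1e-12)


class TestDesign:
    def test_rho_fractions(self):
        d = ConstantRatioDesign("A", "B", ic50_a=10, ic50_b=30)
        assert d.rho_a == pytest.approx(0.25)
        assert d.rho_a + d.rho_b == 1.0

    def test_constant_ratio_at_every_level(self):
        d = ConstantRatioDesign("A", "B", ic50_a=10, ic50_b=30)
        for mult in d.multipliers:
            da, db = d.doses_at(mult)
            assert da / db == pytest.approx(10 / 30)

    @pytest.mark.parametrize("ic50,multipliers,expected", [
        (16.0, (0.125, 0.25, 0.5, 1, 2, 4), (2, 4, 8, 16, 32, 64)),
        (1.0, (0.125, 0.25, 0.5, 1, 2, 4), (0.125, 0.25, 0.5, 1, 2, 4)),
        (7.5, (1,), (7.5,)),
    ])
    def test_dose_series(self, ic50, multipliers, expected):
        assert design_dose_series(ic50, multipliers) == \
            pytest.approx(expected)

    def test_dose_series_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            design_dose_series(0.0)

    def test_metal_complex_ratios(self):
        assert metal_complex_ratio("hexadentate") == Fraction(1, 1)
        assert metal_complex_ratio("tridentate") == Fraction(2, 1)
        with pytest.raises(DomainError):
            metal_complex_ratio("bidentate")


class TestClassification:
    @pytest.mark.parametrize("ci,label", [
        # values with published verbal assignments
        (0.162, "strong synergism"),
        (0.690, "synergism"),
        (1.104, "slight antagonism"),
        (1.183, "slight antagonism"),
        (1.530, "antagonism"),
        # band interiors
        (0.05, "very strong synergism"),
        (0.75, "moderate synergism"),
        (0.87, "slight synergism"),
        (1.0, "nearly additive"),
        (1.3, "moderate antagonism"),
        (5.0, "strong antagonism"),
        (50.0, "very strong antagonism"),
        # boundaries resolve toward the band containing 1
        (0.9, "nearly additive"),
        (1.1, "nearly additive"),
        (0.85, "slight synergism"),
        (1.2, "slight antagonism"),
        (1.45, "moderate antagonism"),
        (3.3, "antagonism"),
        (10.0, "strong antagonism"),
        (0.1, "strong synergism"),
        (0.3, "synergism"),
        (0.7, "moderate synergism"),
    ])
    def test_labels(self, ci, label):
        assert classify_ci(ci).label == label

    def test_rejects_nonpositive(self):
        for bad in (0.0, -1.0, float("nan")):
            with pytest.raises(DomainError):
                classify_ci(bad)

    @given(ci=st.floats(1e-6, 1e6))
    @settings(max_examples=300, deadline=None)
    def test_partition_exactly_one_band(self, ci):
        """Every positive CI falls in exactly one band of the scale."""
        hits = [b for b in CI_SCALE if b.contains(ci)]
        assert len(hits) == 1
        assert classify_ci(ci).label == hits[0].label


class TestFaCICurve:
    def _grid(self):
        return tuple(np.round(np.arange(0.01, 1.0, 0.01), 10))

    def test_sham_curve_is_unity(self):
        model = MedianEffectModel(dm=2.5, m=1.3)
        design = ConstantRatioDesign("A", "A'", ic50_a=2.5, ic50_b=2.5)
        prof = fa_ci_curve(model, model, model, design, self._grid())
        assert np.max(np.abs(np.array(prof.ci_values) - 1.0)) < 1e-9

    def test_matches_bisection_oracle(self):
        """Closed-form curve agrees with numerically inverting the mixture."""
        ma = MedianEffectModel(dm=10, m=1.2)
        mb = MedianEffectModel(dm=20, m=2.4)
        mix = MedianEffectModel(dm=14.0, m=1.7)
        design = ConstantRatioDesign("A", "B", ic50_a=10, ic50_b=20)
        grid = self._grid()
        prof = fa_ci_curve(ma, mb, mix, design, grid)
        for fa, ci in zip(grid, prof.ci_values):
            # oracle: solve predict_fa(mix, D) = fa for D by bisection,
            # then substitute into the CI equation directly
            total = brentq(lambda d: predict_fa(mix, d) - fa,
                           1e-12, 1e12, xtol=1e-300, rtol=1e-15)
            ci_oracle = (design.rho_a * total / dose_for_fa(ma, fa)
                         + design.rho_b * total / dose_for_fa(mb, fa))
            assert ci == pytest.approx(ci_oracle, rel=1e-8)

    def test_equal_dm_different_m_crosses_unity(self):
        """Loewe-additive generation of two agents with equal dm but
        different slopes gives a non-flat, U-shaped CI profile that
        crosses 1: the straight-line mixture fit cannot track the curved
        additive surface everywhere."""
        ma = MedianEffectModel(dm=5.0, m=1.0)
        mb = MedianEffectModel(dm=5.0, m=3.0)
        design = ConstantRatioDesign("A", "B", ic50_a=5.0, ic50_b=5.0)
        # Loewe-additive mixture data: at each total dose, fa solves CI=1
        spec_a, spec_b = AgentSpec("A", 5.0, 1.0), AgentSpec("B", 5.0, 3.0)
        plate = PlateConfig(n_experiments=1, noise_sd=0.0, seed=0,
                            multipliers=tuple(np.logspace(-1.2, 1.2, 12)))
        from combindex import simulate_combination
        from combindex.io_reporting import normalize
        wells = simulate_combination(spec_a, spec_b,
                                     InteractionSpec("A", "B", 1.0), plate)
        wells.attrs["value_kind"] = "signal"
        # mixture over total dose; normalize needs controls -> use viability
        wells["viability"] = wells["signal"]
        wells.attrs["value_kind"] = "viability"
        norm = normalize(wells)
        ds = norm.combination[("A", "B", "exp1")]
        mix = fit_mixture(design, ds)
        prof = fa_ci_curve(ma, mb, mix, design, self._grid())
        ci = np.array(prof.ci_values)
        fa = np.array(prof.fa_grid)
        crossings = np.nonzero(np.diff(np.sign(ci - 1.0)))[0]
        assert len(crossings) >= 1
        # U-shape: both extremes above the interior minimum
        interior = ci[(fa > 0.2) & (fa < 0.8)]
        assert ci[0] > interior.min() and ci[-1] > interior.min()


class TestMixtureFit:
    def test_sham_self_mixture_recovers_model(self):
        ds = noise_free_dataset(1.0, 1.0, agent="A+A")
        design = ConstantRatioDesign("A", "A'", ic50_a=1.0, ic50_b=1.0)
        mix = fit_mixture(design, ds)
        assert mix.dm == pytest.approx(1.0, rel=1e-9)
        assert mix.m == pytest.approx(1.0, rel=1e-9)

    def test_loewe_additive_mixture_refit_reproduces_curve(self):
        """Dense noise-free Loewe-additive mixture points refit to a model
        reproducing the generated dose-response within 1e-6."""
        spec_a, spec_b = AgentSpec("A", 10.0, 1.0), AgentSpec("B", 20.0, 1.0)
        mult = tuple(np.logspace(-1, 1, 15))
        plate = PlateConfig(n_experiments=1, noise_sd=0.0, seed=0,
                            multipliers=mult)
        from combindex import simulate_combination
        wells = simulate_combination(spec_a, spec_b,
                                     InteractionSpec("A", "B", 1.0), plate)
        totals = (wells["dose_a"] + wells["dose_b"]).to_numpy()
        fas = 1.0 - wells["signal"].to_numpy()  # baseline 1, noise-free
        from combindex import DoseResponseDataset
        ds = DoseResponseDataset.from_arrays("A+B", "exp1", totals, fas,
                                             clamp=True)
        design = ConstantRatioDesign("A", "B", ic50_a=10, ic50_b=20)
        mix = fit_mixture(design, ds)
        # equal slopes m=1: Loewe-additive mixture is exactly median-effect
        # with dm solving rho_a/dxa + rho_b/dxb parameterization
        for total, fa in zip(totals, fas):
            if 0.02 < fa < 0.98:
                assert predict_fa(mix, total) == pytest.approx(fa, abs=1e-6)

    def test_noisy_mixture_fits_are_finite(self):
        spec_a, spec_b = AgentSpec("A", 10.0, 1.5), AgentSpec("B", 20.0, 2.0)
        plate = PlateConfig(n_experiments=4, noise_sd=0.05, seed=7)
        from combindex import simulate_combination
        from combindex.io_reporting import normalize
        wells = simulate_combination(spec_a, spec_b,
                                     InteractionSpec("A", "B", 0.8), plate)
        wells["viability"] = wells["signal"]
        wells.attrs["value_kind"] = "viability"
        norm = normalize(wells)
        design = ConstantRatioDesign("A", "B", ic50_a=10, ic50_b=20)
        for exp in ("exp1", "exp2", "exp3", "exp4"):
            mix = fit_mixture(design, norm.combination[("A", "B", exp)])
            assert np.isfinite(mix.dm) and np.isfinite(mix.m)
            assert mix.dm > 0 and mix.m > 0


class TestCIAtDesignPoint:
    def test_identical_noise_free_experiments_all_additive(self):
        model = MedianEffectModel(dm=4.0, m=2.0)
        design = ConstantRatioDesign("A", "A'", ic50_a=4.0, ic50_b=4.0)
        fa_at_ic50_point = predict_fa(model, 8.0)  # total dose 2 x dm
        per_exp = {f"exp{i}": (model, model, fa_at_ic50_point)
                   for i in range(1, 5)}
        results, failures = ci_at_design_point(design, 1.0, per_exp)
        assert not failures
        assert len(results) == 4
        for res in results.values():
            assert res.ci == pytest.approx(1.0, abs=1e-9)

    def test_invalid_experiments_reported_not_dropped(self):
        model = MedianEffectModel(dm=4.0, m=2.0)
        design = ConstantRatioDesign("A", "B", ic50_a=4.0, ic50_b=4.0)
        per_exp = {"good": (model, model, 0.6),
                   "bad": (model, model, 1.0)}
        results, failures = ci_at_design_point(design, 1.0, per_exp)
        assert set(results) == {"good"}
        assert set(failures) == {"bad"}


class TestAggregate:
    def test_identical_values(self):
        agg = aggregate([1.0, 1.0, 1.0, 1.0])
        assert (agg.mean, agg.sd, agg.n) == (1.0, 0.0, 4)

    def test_sample_sd_uses_n_minus_1(self):
        agg = aggregate([2, 4, 4, 4, 5, 5, 7, 9])
        assert agg.mean == pytest.approx(5.0)
        assert agg.sd == pytest.approx(2.13809, rel=1e-5)

    def test_single_value_flags_undefined_sd(self):
        agg = aggregate([0.5])
        assert agg.mean == 0.5 and agg.n == 1
        assert np.isnan(agg.sd)
        assert "sd-undefined-n1" in agg.flags

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            aggregate([])


class TestConstantCIRecovery:
    @pytest.mark.parametrize("ci_star", [0.1, 0.3, 0.5, 1.0, 1.5, 3.0])
    def test_noise_free_recovery_exact(self, ci_star, two_agent_panel,
                                       noise_free_plate):
        study = generate_study(two_agent_panel,
                               [InteractionSpec("A", "B", ci_star)],
                               noise_free_plate)
        rep = run_study(study.wells, make_plots=False)
        assert len(rep.ci_table) == 6
        assert np.allclose(rep.ci_table["ci_mean"], ci_star, atol=1e-6)

    @pytest.mark.parametrize("ci_star", [0.3, 1.0, 3.0])
    def test_noisy_recovery_within_15_percent(self, ci_star,
                                              two_agent_panel):
        plate = PlateConfig(n_experiments=4, noise_sd=0.05, seed=42)
        study = generate_study(two_agent_panel,
                               [InteractionSpec("A", "B", ci_star)],
                               plate)
        rep = run_study(study.wells, make_plots=False)
        at_ic50 = rep.ci_table[rep.ci_table["multiplier"] == 1.0]
        assert float(at_ic50["ci_mean"].iloc[0]) == \
            pytest.approx(ci_star, rel=0.15)
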