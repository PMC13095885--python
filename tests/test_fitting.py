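"""Calibration pipeline: regression oracles, breakpoint recovery, outlier
flagging, per-group curve fits and species-level assembly."""

import numpy as np
import pytest

from leafsize import (
    CalibrationConfig,
    CalibrationError,
    DegenerateDataError,
    GroupSizeError,
    NoiseSpec,
    SimConfig,
    SpeciesId,
    TlnGroup,
    Trait,
    calibrate_species,
    default_init,
    default_parameter_set,
    evaluate_fit,
    fit_profile,
    fit_tln_linear,
    fit_tln_plateau,
    fit_tln_segmented,
    flag_dr_outliers,
    generate_dataset,
)

from conftest import noiseless_group, random_profile_params


def ols_oracle(points):
    """Closed-form simple-regression coefficients via the normal equations."""
    t = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    slope = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
    return y.mean() - slope * t.mean(), slope


class TestTlnLinear:
    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.uniform(8, 40, size=12)
            y = 2.0 + 0.5 * t + rng.normal(0, 1, size=12)
            points = list(zip(t, y))
            res = fit_tln_linear(points)
            a, b = ols_oracle(points)
            assert res.rule.intercept == pytest.approx(a, abs=1e-10)
            assert res.rule.slope == pytest.approx(b, abs=1e-10)

    def test_exact_line_recovery(self):
        points = [(t, 1.10 + 0.47 * t) for t in range(11, 26)]
        res = fit_tln_linear(points)
        assert res.rule.intercept == pytest.approx(1.10, abs=1e-9)
        assert res.rule.slope == pytest.approx(0.47, abs=1e-9)
        assert res.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_single_tln_value_is_rank_deficient(self):
        with pytest.raises(DegenerateDataError):
            fit_tln_linear([(15, 8.0), (15, 8.1), (15, 8.2)])


class TestTlnSegmented:
    def test_recovers_sorghum_rule_with_free_breakpoint(self, sorghum_set):
        rule = sorghum_set.trait(Trait.BLADE_LENGTH).xs_rule
        points = [(t, rule(t)) for t in range(14, 31)]
        res = fit_tln_segmented(points)
        assert res.rule.breakpoint == pytest.approx(20.5, abs=1e-6)
        assert res.rule.slope_low == pytest.approx(0.46, abs=1e-6)
        assert res.rule.slope_high == pytest.approx(0.26, abs=1e-6)
        assert res.rule.intercept == pytest.approx(4.64, abs=1e-6)
        assert res.residual_sd < 1e-8

    def test_fixed_breakpoint_mode(self, sorghum_set):
        rule = sorghum_set.trait(Trait.BLADE_WIDTH).xs_rule
        points = [(t, rule(t)) for t in range(14, 31)]
        res = fit_tln_segmented(points, breakpoint=20.5)
        assert res.rule.slope_low == pytest.approx(0.25, abs=1e-9)
        assert res.rule.slope_high == pytest.approx(0.20, abs=1e-9)

    def test_equal_slopes_flagged_degenerate(self):
        points = [(t, 1.0 + 0.3 * t) for t in range(10, 30)]
        res = fit_tln_segmented(points, breakpoint=20.0)
        assert res.degenerate
        assert res.rule.slope_low == pytest.approx(res.rule.slope_high, abs=1e-6)

    def test_one_sided_data_falls_back_to_linear(self):
        points = [(t, 1.0 + 0.3 * t) for t in range(10, 18)]
        with pytest.warns(UserWarning, match="one side"):
            res = fit_tln_segmented(points, breakpoint=30.0)
        assert res.degenerate
        assert res.rule.slope_low == pytest.approx(0.3, abs=1e-8)


class TestTlnPlateau:
    def test_recovers_maize_length_rule(self, maize_set):
        rule = maize_set.trait(Trait.BLADE_LENGTH).dr_rule
        points = [(t, rule(t)) for t in range(10, 23)]
        res = fit_tln_plateau(points)
        assert res.rule.breakpoint == pytest.approx(17.63, abs=1e-5)
        assert res.rule.intercept == pytest.approx(2.88, abs=1e-6)
        assert res.rule.slope == pytest.approx(-0.13, abs=1e-6)
        assert res.residual_sd < 1e-8

    def test_flat_series_flagged_degenerate(self):
        res = fit_tln_plateau([(t, 0.5) for t in range(10, 20)])
        assert res.degenerate
        assert res.rule.slope == 0.0

    def test_monotone_decline_pins_breakpoint_at_max(self):
        points = [(t, 5.0 - 0.2 * t) for t in range(10, 20)]
        with pytest.warns(UserWarning, match="plateau"):
            res = fit_tln_plateau(points)
        assert res.rule.breakpoint == pytest.approx(19.0)
        assert res.rule.slope == pytest.approx(-0.2, abs=1e-8)


class TestDrOutliers:
    @staticmethod
    def bilinear_points(rng=None):
        rule = lambda t: 2.88 - 0.13 * min(t, 17.63)
        pts = [[t, rule(t)] for t in range(10, 23)]
        if rng is not None:
            for p in pts:
                p[1] += rng.normal(0, 0.02)
        return np.array(pts)

    def test_inflated_point_is_the_only_flag(self):
        rng = np.random.default_rng(11)
        pts = self.bilinear_points(rng)
        pts[4, 1] *= 10.0
        mask = flag_dr_outliers(pts)
        assert mask[4]
        assert mask.sum() == 1

    def test_clean_trend_never_flagged(self):
        assert not flag_dr_outliers(self.bilinear_points()).any()

    def test_identical_points_not_flagged(self):
        assert not flag_dr_outliers([(15, 0.5)] * 8).any()

    def test_quantile_one_disables_flagging(self):
        rng = np.random.default_rng(11)
        pts = self.bilinear_points(rng)
        pts[4, 1] *= 10.0
        assert not flag_dr_outliers(pts, quantile=1.0).any()

    def test_too_few_points_warns_and_flags_nothing(self):
        with pytest.warns(UserWarning, match="fewer"):
            mask = flag_dr_outliers([(10, 1.0), (12, 0.9), (14, 0.8)])
        assert not mask.any()


class TestEvaluateFit:
    def test_perfect_prediction(self):
        out = evaluate_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out == {"rmse": 0.0, "r2": 1.0}

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0])
        out = evaluate_fit(obs, np.full(3, obs.mean()))
        assert out["r2"] == pytest.approx(0.0)

    def test_hand_computed_rmse(self):
        out = evaluate_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert out["rmse"] == pytest.approx(np.sqrt(1.0 / 3.0), rel=1e-12)

    def test_zero_variance_observations(self):
        with pytest.warns(UserWarning, match="variance"):
            out = evaluate_fit([2.0, 2.0, 2.0], [2.0, 2.1, 1.9])
        assert np.isnan(out["r2"])


class TestDefaultInit:
    def test_monotone_data_puts_xs_at_last_position(self):
        pos = np.arange(1, 13, dtype=float)
        group = TlnGroup(SpeciesId.MAIZE, "g", Trait.BLADE_LENGTH, 12, pos, pos * 10)
        assert default_init(group).xs == 12.0

    def test_xs_at_observed_peak(self, maize_set):
        group = noiseless_group(maize_set, Trait.BLADE_LENGTH, 17)
        init = default_init(group)
        assert init.xs == 10.0  # per-position maximum of the TLN-17 profile
        assert init.L1 == pytest.approx(group.values.min())

    def test_init_always_valid_on_random_groups(self):
        rng = np.random.default_rng(5)
        from leafsize import leaf_dimension

        for p in random_profile_params(rng, 300):
            tln = int(min(max(p.xs + rng.integers(2, 8), 9), 40))
            pos = np.arange(1, tln + 1, dtype=float)
            vals = leaf_dimension(pos, p) * rng.uniform(0.8, 1.2, size=tln)
            group = TlnGroup(SpeciesId.MAIZE, "g", Trait.BLADE_LENGTH, tln, pos, vals)
            default_init(group).validate()  # raises on violation


class TestFitProfile:
    def test_noiseless_recovery_is_exact(self, maize_set):
        group = noiseless_group(maize_set, Trait.BLADE_LENGTH, 17)
        res = fit_profile(group)
        assert res.converged
        assert res.rss / res.n < 1e-6
        truth = dict(L1=51.18, cm=123.84, rm=1.17, tb=2.02, xs=9.09, dr=0.67,
                     dsl=12.53)
        for name, value in truth.items():
            assert getattr(res.params, name) == pytest.approx(value, rel=0.02)

    def test_sorghum_first_leaf_recovery(self, sorghum_set):
        group = noiseless_group(sorghum_set, Trait.BLADE_LENGTH, 18)
        res = fit_profile(group)
        assert res.params.L1 == pytest.approx(17.59, rel=0.02)

    def test_goodness_of_fit_bookkeeping(self, maize_set):
        group = noiseless_group(maize_set, Trait.BLADE_LENGTH, 19)
        res = fit_profile(group)
        assert res.rmse == pytest.approx(np.sqrt(res.rss / res.n))
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_observations(self, maize_set):
        group = TlnGroup(
            SpeciesId.MAIZE, "g", Trait.BLADE_LENGTH, 17,
            np.arange(1.0, 6.0), np.arange(1.0, 6.0) * 30,
        )
        with pytest.raises(GroupSizeError):
            fit_profile(group)

    def test_permutation_invariance(self, maize_set):
        rng = np.random.default_rng(0)
        pos = np.arange(1.0, 18.0)
        from leafsize import build_params, leaf_dimension

        vals = leaf_dimension(pos, build_params(maize_set, Trait.BLADE_LENGTH, 17))
        vals = vals * (1 + 0.03 * rng.standard_normal(17))
        perm = rng.permutation(17)
        res_a = fit_profile(
            TlnGroup(SpeciesId.MAIZE, "g", Trait.BLADE_LENGTH, 17, pos, vals)
        )
        res_b = fit_profile(
            TlnGroup(SpeciesId.MAIZE, "g", Trait.BLADE_LENGTH, 17, pos[perm],
                     vals[perm])
        )
        for name in ("L1", "cm", "rm", "tb", "xs", "dr", "dsl"):
            assert getattr(res_a.params, name) == pytest.approx(
                getattr(res_b.params, name), abs=1e-10
            )


class TestCalibrateSpecies:
    def test_single_tln_dataset_is_rejected(self):
        cfg = SimConfig(
            species=SpeciesId.MAIZE, tln_values=[17],
            noise=NoiseSpec(length_sd=0.0, width_sd=0.0), seed=0,
        )
        records, _ = generate_dataset(cfg)
        with pytest.raises(CalibrationError):
            calibrate_species(records)

    def test_mixed_species_rejected(self):
        a, _ = generate_dataset(SimConfig(
            species=SpeciesId.MAIZE, tln_values=[15, 16, 17, 18],
            noise=NoiseSpec(length_sd=0.0, width_sd=0.0), seed=0))
        b, _ = generate_dataset(SimConfig(
            species=SpeciesId.SORGHUM, tln_values=[15, 16, 17, 18],
            noise=NoiseSpec(length_sd=0.0, width_sd=0.0), seed=0))
        import pandas as pd

        with pytest.raises(CalibrationError, match="one species"):
            calibrate_species(pd.concat([a, b], ignore_index=True))

    def test_noiseless_maize_subset_recovers_cm(self, maize_set):
        cfg = SimConfig(
            species=SpeciesId.MAIZE, tln_values=list(range(14, 22)),
            noise=NoiseSpec(length_sd=0.0, width_sd=0.0), seed=0,
        )
        records, _ = generate_dataset(cfg)
        result = calibrate_species(records)
        trait = result.parameter_set.trait(Trait.BLADE_LENGTH)
        assert trait.cm == pytest.approx(123.84, rel=0.02)
        assert trait.L1 == pytest.approx(51.18, rel=0.02)
        assert result.parameter_set.trait(Trait.BLADE_WIDTH).L1 == pytest.approx(
            15.98, rel=0.02
        )
        assert (result.group_results["rmse"] < 1e-5).all()
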