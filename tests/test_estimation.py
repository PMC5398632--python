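"""The three A-estimators and the nested-model comparisons."""

import numpy as np
import pandas as pd
import pytest

from ttgrae import (
    MONTHLY_SPAN_SCALE,
    ProbitPointSet,
    TTGParams,
    compare_models,
    endpoint_estimate,
    month_grid,
    per_level_regression,
    probit_upper,
    selection_probability,
    stacked_regression,
    selection_points,
)


def noiseless_points(params: TTGParams, t, criteria, grid_n=500.0) -> ProbitPointSet:
    """Exact model-consistent probit points at birthtimes ``t`` for each
    criterion in ``criteria`` (a poor man's forward model, kept independent
    of the tabulation pipeline)."""
    rows = []
    for k, c in enumerate(criteria):
        for ti in np.asarray(t, float):
            p = selection_probability(TTGParams(params.A, c), ti)
            rows.append(
                {"t_B": ti, "level": f"L{k}", "p": p, "z": probit_upper(p), "n": grid_n}
            )
    return ProbitPointSet(frame=pd.DataFrame(rows))


class TestEndpointEstimate:
    def test_classroom_worked_example(self, speaking_points):
        fit = endpoint_estimate(speaking_points, span_scale=MONTHLY_SPAN_SCALE)
        diffs = [round(v, 4) for v in fit.per_level.values()]
        assert diffs == [0.6552, 0.4921, 0.8043, 0.5204]
        assert round(fit.A, 4) == 0.6742

    def test_recovers_truth_on_noiseless_data(self):
        truth = TTGParams(0.8, 0.5)
        t = np.linspace(0.1, 0.9, 5)
        pts = noiseless_points(truth, t, criteria=[0.5, 1.1])
        fit = endpoint_estimate(pts, span_scale=1.0 / (t[-1] - t[0]))
        assert fit.A == pytest.approx(0.8, abs=1e-10)

    def test_flat_z_gives_zero(self):
        pts = noiseless_points(TTGParams(0.0, 1.0), [0.0, 1.0], criteria=[1.0])
        assert endpoint_estimate(pts).A == pytest.approx(0.0, abs=1e-12)

    def test_level_missing_an_endpoint_is_skipped(self, speaking_points):
        frame = speaking_points.frame
        trimmed = frame[~((frame["level"] == ">= 5") & (frame["t_B"] > 0.9))]
        fit = endpoint_estimate(
            ProbitPointSet(frame=trimmed), span_scale=MONTHLY_SPAN_SCALE
        )
        assert ">= 5" not in fit.per_level
        assert any(">= 5" in w for w in fit.warnings)


class TestPerLevelRegression:
    def test_classroom_worked_example(self, speaking_points):
        fit = per_level_regression(speaking_points)
        slopes = [round(v, 4) for v in fit.per_level.values()]
        assert slopes == [0.6716, 0.5965, 0.7441, 0.5583]
        assert round(fit.A, 4) == 0.6426

    def test_recovers_truth_on_noiseless_data(self):
        pts = noiseless_points(TTGParams(0.66, -1.0), np.linspace(0, 1, 12), [0.2, 0.9])
        fit = per_level_regression(pts)
        for slope in fit.per_level.values():
            assert slope == pytest.approx(0.66, abs=1e-10)

    def test_single_point_level_skipped(self):
        pts = noiseless_points(TTGParams(0.5, 0.0), [0.2, 0.8], [0.0])
        lone = pts.frame.iloc[:1].assign(level="lonely")
        merged = ProbitPointSet(frame=pd.concat([pts.frame, lone]))
        fit = per_level_regression(merged)
        assert "lonely" not in fit.per_level


class TestStackedRegression:
    def test_classroom_fit(self, speaking_points):
        fit = stacked_regression(speaking_points)
        assert round(fit.A, 3) == 0.643
        assert round(fit.t_A, 2) == 13.08
        assert fit.df == 43
        assert round(fit.R2, 3) == 0.995
        assert fit.p_A < 1e-15
        assert fit.n_points == 48

    def test_academy_three_point_fit(self, academy_points):
        fit = stacked_regression(academy_points)
        assert round(fit.A, 3) == 0.689
        assert round(fit.C, 3) == 2.429
        assert round(fit.R2, 4) == 0.9987
        assert fit.df == 1

    def test_recovers_truth_and_offsets_on_noiseless_data(self):
        truth = TTGParams(0.8, 0.5)
        pts = noiseless_points(truth, np.linspace(0, 1, 6), criteria=[0.5, 1.3])
        fit = stacked_regression(pts)
        assert fit.A == pytest.approx(0.8, abs=1e-10)
        assert fit.C == pytest.approx(0.5, abs=1e-10)
        assert fit.level_offsets["L1"] == pytest.approx(0.8, abs=1e-10)

    def test_rank_deficiency_names_column(self):
        frame = pd.DataFrame(
            {
                "t_B": [0.2, 0.2, 0.8, 0.8],
                "level": ["a", "b", "a", "b"],
                "p": [0.3, 0.3, 0.2, 0.2],
                "z": [0.5, 0.5, 0.8, 0.8],
                "n": [10] * 4,
            }
        )
        # make the dummy collinear with the intercept by using one level only
        degenerate = frame.assign(t_B=[0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="collinear"):
            stacked_regression(ProbitPointSet(frame=degenerate))


class TestEstimatorAgreement:
    def test_all_three_identical_on_noiseless_model_data(self):
        truth = TTGParams(0.73, 0.21)
        t = month_grid("Sep", 365).midpoints
        pts = noiseless_points(truth, t, criteria=[0.21, 0.9, 1.6])
        a_end = endpoint_estimate(pts, span_scale=1.0 / (t[-1] - t[0])).A
        a_lvl = per_level_regression(pts).A
        a_stk = stacked_regression(pts).A
        assert a_end == pytest.approx(truth.A, abs=1e-8)
        assert a_lvl == pytest.approx(truth.A, abs=1e-8)
        assert a_stk == pytest.approx(truth.A, abs=1e-8)

    def test_stacked_equals_mean_of_per_level_slopes_when_balanced(self, speaking_points):
        # every level shares the same 12 birthtimes, so the stacked slope
        # must equal the unweighted mean of the per-level slopes
        assert stacked_regression(speaking_points).A == pytest.approx(
            per_level_regression(speaking_points).A, abs=1e-10
        )


class TestCompareModels:
    def test_classroom_quadratic_and_interaction(self, speaking_points):
        quad = compare_models(speaking_points, "quadratic")
        assert round(quad.F, 2) == 2.32
        assert (quad.df1, quad.df2) == (1, 42)
        inter = compare_models(speaking_points, "interaction")
        assert inter.F < 1.0
        assert (inter.df1, inter.df2) == (3, 40)

    def test_exact_linear_data_gives_zero_F(self):
        pts = noiseless_points(TTGParams(0.8, 0.5), np.linspace(0, 1, 8), [0.5, 1.1])
        assert compare_models(pts, "quadratic").F == 0.0

    def test_quadratic_truth_detected(self):
        """z(t) = C + A·t + 2·t² with small noise is flagged at alpha=0.01."""
        rng = np.random.default_rng(42)
        t = np.tile(month_grid("Sep").midpoints, 2)
        level = np.repeat(["a", "b"], 12)
        offset = np.where(level == "b", 0.7, 0.0)
        rejections = 0
        reps = 500
        for _ in range(reps):
            z = 0.5 + 0.8 * t + 2.0 * t ** 2 + offset + rng.normal(0, 0.05, t.size)
            frame = pd.DataFrame(
                {"t_B": t, "level": level, "p": 0.5, "z": z, "n": 100.0}
            )
            cmp_res = compare_models(ProbitPointSet(frame=frame), "quadratic")
            rejections += cmp_res.p < 0.01
        assert rejections / reps > 0.95

    def test_null_calibration_on_independent_points(self):
        """With independent binomial points and a true linear model, the
        quadratic test rejects at about its nominal 5% level."""
        import ttgrae

        rng = np.random.default_rng(5)
        grid = month_grid("Sep", 365, pools=[5000] * 12)
        spec = ttgrae.SimulationSpec(params=TTGParams(0.8, 0.0), grid=grid, seed=1)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            sel = ttgrae.simulate_counts(spec, rng=rng)
            pts = selection_points(grid, selected=sel)
            rejections += compare_models(pts, "quadratic").p < 0.05
        assert abs(rejections / reps - 0.05) < 0.02

    def test_insufficient_df_rejected(self, academy_points):
        with pytest.raises(ValueError, match="degrees of freedom"):
            compare_models(academy_points, "quadratic")


class TestParameterRecoveryBias:
    def test_classroom_scale_binomial_sampling_is_nearly_unbiased(self):
        """Mean bias of the stacked  over seeded replicates stays below 0.02
        at classroom-like monthly sample sizes."""
        import ttgrae

        grid = month_grid("Sep", 365, pools=[450] * 12)
        spec = ttgrae.SimulationSpec(
            params=TTGParams(0.8, -2.5),
            grid=grid,
            criteria=(-2.5, -1.2, 0.0, 1.0),
            seed=7,
            replicates=1000,
        )
        report = ttgrae.recover_parameters(spec)
        assert abs(report.bias_A) < 0.02
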