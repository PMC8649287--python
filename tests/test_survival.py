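"""Cox machinery: Lexis splitting, partial likelihood, floated risks,
splines, decade HRs and subgroup analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import sbpvar as sv
from sbpvar import pipeline
from sbpvar import survival as srv


class TestVariabilityGroups:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (9.0, "<10"),
            (10.0, "10-11.9"),
            (11.95, "10-11.9"),
            (12.0, "12-13.9"),
            (14.0, "14-15.9"),
            (15.999, "14-15.9"),
            (16.0, ">=16"),
            (17.4, ">=16"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert srv.assign_variability_group(value) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            srv.assign_variability_group(0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.01, max_value=60.0))
    def test_always_one_of_five_groups(self, x):
        assert srv.assign_variability_group(x) in srv.VARIABILITY_GROUPS


class TestLexisSplit:
    def test_boundary_arithmetic_example(self):
        s = pd.DataFrame({"subject_id": [1], "age": [53.2], "time": [4.0], "event": [1]})
        ep = srv.lexis_split(s)
        assert len(ep) == 2
        assert ep.iloc[0][["entry_age", "exit_age"]].tolist() == [53.2, 55.0]
        assert ep.iloc[0]["age_band"] == "45-54"
        assert ep.iloc[0]["event"] == 0
        assert ep.iloc[1][["entry_age", "exit_age"]].tolist() == [55.0, 57.2]
        assert ep.iloc[1]["age_band"] == "55-64"
        assert ep.iloc[1]["event"] == 1

    def test_conservation(self, survival_cohort):
        _, truths = survival_cohort
        ep = srv.lexis_split(truths)
        assert np.isclose(
            (ep["exit"] - ep["entry"]).sum(), truths["time"].sum(), rtol=1e-12
        )
        assert ep["event"].sum() == truths["event"].sum()
        # episodes of one subject are disjoint and contiguous
        g = ep.groupby("subject_id")
        assert (g["entry"].min() == 0).all()
        for _, sub in list(g)[:20]:
            assert np.allclose(sub["exit"].to_numpy()[:-1], sub["entry"].to_numpy()[1:])

    def test_personyears_match_daily_tally(self, survival_cohort):
        _, truths = survival_cohort
        sub = truths.head(500)
        ep = srv.lexis_split(sub)
        got = ep.groupby("age_band").apply(
            lambda d: (d["exit"] - d["entry"]).sum(), include_groups=False
        )
        # brute-force: walk each follow-up day and bin by attained age
        tally = {b: 0.0 for b in srv.AGE_BANDS}
        step = 1.0 / 365.0
        for _, row in sub.iterrows():
            days = np.arange(0.0, row["time"], step)
            ages = row["age"] + days + step / 2
            idx = np.clip(((ages - 45) // 10).astype(int), 0, 3)
            for i, b in enumerate(srv.AGE_BANDS):
                tally[b] += step * (idx == i).sum()
        for b in srv.AGE_BANDS:
            assert abs(got.get(b, 0.0) - tally[b]) < len(sub) / 365.0

    def test_age_above_84_stays_in_top_band(self):
        s = pd.DataFrame({"subject_id": [1], "age": [83.0], "time": [8.0], "event": [0]})
        ep = srv.lexis_split(s)
        assert (ep["age_band"] == "75-84").all()
        assert ep["exit_age"].max() == pytest.approx(91.0)

    def test_negative_followup_rejected(self):
        s = pd.DataFrame({"subject_id": [1], "age": [50.0], "time": [-1.0], "event": [0]})
        with pytest.raises(ValueError):
            srv.lexis_split(s)


def _toy_no_ties():
    return pd.DataFrame(
        {
            "entry": [0.0] * 6,
            "exit": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 0],
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )


class TestFitCox:
    def test_matches_grid_search_oracle(self):
        toy = _toy_no_ties()
        fit = srv.fit_cox(toy, ["x"])
        grid = np.linspace(-3, 3, 60001)
        ll = np.zeros_like(grid)
        for i in range(len(toy)):
            if toy["event"][i]:
                risk = toy.loc[toy["exit"] >= toy["exit"][i], "x"].to_numpy()
                ll += grid * toy["x"][i] - np.log(
                    np.exp(np.outer(grid, risk)).sum(axis=1)
                )
        best = grid[np.argmax(ll)]
        assert fit.params["x"] == pytest.approx(best, abs=1e-4)
        assert fit.gradient_norm < 1e-8

    def test_label_swap_symmetry(self):
        # two groups whose event patterns are exact mirror images
        df = pd.DataFrame(
            {
                "entry": [0.0] * 8,
                "exit": [1, 2, 3, 4, 1, 2, 3, 4],
                "event": [1, 0, 1, 0, 1, 0, 1, 0],
                "x": [0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0],
            }
        )
        fit = srv.fit_cox(df, ["x"])
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-10)

    def test_ties_match_hand_expanded_likelihoods(self):
        toy = pd.DataFrame(
            {
                "entry": [0.0] * 5,
                "exit": [1.0, 1.0, 2.0, 2.0, 3.0],
                "event": [1, 1, 1, 0, 0],
                "x": [1.0, 0.0, 1.0, 0.0, 1.0],
            }
        )
        x = toy["x"].to_numpy()

        def neg_breslow(b):
            w = np.exp(b * x)
            ll = b * (1 + 0) - 2 * np.log(w.sum())
            ll += b * 1 - np.log(w[2:].sum())
            return -ll

        def neg_efron(b):
            w = np.exp(b * x)
            s0d = w[0] + w[1]
            ll = b * (1 + 0) - np.log(w.sum()) - np.log(w.sum() - 0.5 * s0d)
            ll += b * 1 - np.log(w[2:].sum())
            return -ll

        fb = srv.fit_cox(toy, ["x"], ties="breslow")
        fe = srv.fit_cox(toy, ["x"], ties="efron")
        b_or = minimize_scalar(neg_breslow, bounds=(-5, 5), method="bounded").x
        e_or = minimize_scalar(neg_efron, bounds=(-5, 5), method="bounded").x
        assert fb.params["x"] == pytest.approx(b_or, abs=1e-5)
        assert fe.params["x"] == pytest.approx(e_or, abs=1e-5)
        assert abs(fe.params["x"] - fb.params["x"]) > 1e-6
        assert fb.loglik == pytest.approx(-neg_breslow(fb.params["x"]), rel=1e-10)
        assert fe.loglik == pytest.approx(-neg_efron(fe.params["x"]), rel=1e-10)

    def test_matches_lifelines_with_left_truncation(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        t = np.round(rng.exponential(np.exp(-0.5 * x1 + 0.3 * x2)), 1) + 0.1
        c = rng.uniform(0.2, 3, n)
        entry = rng.uniform(0, 0.05, n)
        df = pd.DataFrame(
            {
                "entry": entry,
                "exit": np.minimum(t, c) + entry,
                "event": (t <= c).astype(int),
                "x1": x1,
                "x2": x2,
            }
        )
        mine = srv.fit_cox(df, ["x1", "x2"])
        cph = lifelines.CoxPHFitter()
        cph.fit(
            df, entry_col="entry", duration_col="exit", event_col="event",
            formula="x1 + x2",
        )
        assert np.allclose(mine.params.to_numpy(), cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(mine.se().to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-5)
        assert mine.loglik == pytest.approx(cph.log_likelihood_, rel=1e-9)

    def test_loglik_improves_on_null(self, survival_cohort):
        _, truths = survival_cohort
        ep, bands = pipeline.make_episodes(truths)
        fit = srv.fit_cox(ep, ["sigma_i", "male", "age"] + bands)
        with pytest.warns(UserWarning):  # null fit reports its frozen iteration
            null = srv.fit_cox(ep, ["sigma_i", "male", "age"] + bands, max_iter=0)
        assert fit.loglik >= null.loglik
        assert fit.gradient_norm < 1e-8
        cov = fit.cov.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_constant_covariate_rejected(self):
        toy = _toy_no_ties()
        toy["z"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            srv.fit_cox(toy, ["x", "z"])

    def test_no_events_rejected(self):
        toy = _toy_no_ties()
        toy["event"] = 0
        with pytest.raises(ValueError):
            srv.fit_cox(toy, ["x"])

    def test_separation_reported(self):
        # covariate perfectly ordered with event times: monotone likelihood
        df = pd.DataFrame(
            {
                "entry": [0.0] * 4,
                "exit": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
                "x": [4.0, 3.0, 2.0, 1.0],
            }
        )
        with pytest.warns(UserWarning):
            fit = srv.fit_cox(df, ["x"], max_iter=60)
        assert fit.warnings


class TestPer5:
    def test_null_maps_to_unit_hr(self, survival_cohort):
        _, truths = survival_cohort
        ep, bands = pipeline.make_episodes(truths)
        fit = srv.fit_cox(ep, ["sigma_i", "male"] + bands)
        fit.params["sigma_i"] = 0.0
        assert srv.per5_continuous_hr(fit, "sigma_i")["hr"] == pytest.approx(1.0)

    def test_inverse_mapping(self, survival_cohort):
        _, truths = survival_cohort
        ep, bands = pipeline.make_episodes(truths)
        fit = srv.fit_cox(ep, ["sigma_i", "male"] + bands)
        fit.params["sigma_i"] = np.log(1.27) / 5
        assert srv.per5_continuous_hr(fit, "sigma_i")["hr"] == pytest.approx(1.27)

    def test_absent_covariate_rejected(self, survival_cohort):
        _, truths = survival_cohort
        ep, bands = pipeline.make_episodes(truths)
        fit = srv.fit_cox(ep, ["sigma_i"] + bands)
        with pytest.raises(KeyError):
            srv.per5_continuous_hr(fit, "not_there")


class TestDecadeGeometric:
    def test_equal_halves_idempotent(self):
        d = srv.decade_hr_geometric(np.log(1.4), np.log(1.4), 0.01, 0.01)
        assert d["hr"] == pytest.approx(1.4)

    def test_worked_example(self):
        d = srv.decade_hr_geometric(np.log(1.2), np.log(1.8), 0.01, 0.04)
        assert d["hr"] == pytest.approx(np.sqrt(2.16), rel=1e-12)
        assert d["var"] == pytest.approx(0.0125, rel=1e-12)

    def test_perfect_anticorrelation_zero_variance(self):
        d = srv.decade_hr_geometric(0.1, 0.2, 0.02, 0.02, c12=-0.02)
        assert d["var"] == pytest.approx(0.0, abs=1e-15)

    def test_variance_matches_parametric_bootstrap(self):
        rng = np.random.default_rng(1)
        b1, b2, v1, v2, c12 = np.log(1.2), np.log(1.8), 0.01, 0.04, 0.004
        d = srv.decade_hr_geometric(b1, b2, v1, v2, c12)
        draws = rng.multivariate_normal([b1, b2], [[v1, c12], [c12, v2]], 200000)
        boot = ((draws[:, 0] + draws[:, 1]) / 2).var()
        assert d["var"] == pytest.approx(boot, rel=0.05)


class _StubFit:
    def __init__(self, params, cov):
        names = list(params)
        self.params = pd.Series(params)
        self.cov = pd.DataFrame(cov, index=names, columns=names)


class TestFloatedRisks:
    def test_symmetric_case_exact(self):
        f = _StubFit({"a": 0.1, "b": 0.2}, np.eye(2) * 0.05)
        fr = srv.floated_absolute_risks(f, ["a", "b"], reference="ref")
        assert fr.table["floated_var"].to_numpy() == pytest.approx(
            [0.0, 0.05, 0.05], abs=1e-12
        )
        assert fr.max_pair_residual < 1e-12

    def test_correlated_linear_system(self):
        f = _StubFit({"a": 0.2, "b": 0.5}, [[0.02, 0.01], [0.01, 0.03]])
        fr = srv.floated_absolute_risks(f, ["a", "b"])
        assert fr.table["floated_var"].to_numpy() == pytest.approx(
            [0.01, 0.01, 0.02], abs=1e-12
        )

    def test_reference_carries_interval(self):
        f = _StubFit({"a": 0.2, "b": 0.5}, [[0.02, 0.01], [0.01, 0.03]])
        fr = srv.floated_absolute_risks(f, ["a", "b"], reference="<10")
        row = fr.table.iloc[0]
        assert row["group"] == "<10"
        assert row["hr"] == 1.0
        assert row["hr_lo"] < 1.0 < row["hr_hi"]

    def test_pairwise_reproduction_on_model_fit(self, survival_cohort):
        _, truths = survival_cohort
        truths = truths.copy()
        truths["vgroup"] = srv.assign_variability_group(truths["sigma_i"])
        ep, bands = pipeline.make_episodes(truths)
        grp, ref = pipeline._add_dummies(ep, "vgroup", srv.VARIABILITY_GROUPS, "grp_")
        fit = srv.fit_cox(ep, grp + ["alpha_i", "male", "age"] + bands)
        fr = srv.floated_absolute_risks(fit, grp, reference=ref)
        assert fr.relative_residual < 0.10
        # positive log-linear truth: floated log HRs increase across groups
        assert np.all(np.diff(fr.table["log_hr"].to_numpy()) > 0)

    def test_underdetermined_rejected(self):
        f = _StubFit({"a": 0.2}, [[0.02]])
        with pytest.raises(ValueError):
            srv.floated_absolute_risks(f, ["a"])


class TestRcsBasis:
    KNOTS = (10.0, 12.7, 16.0)

    def test_zero_below_first_knot(self):
        B = srv.rcs_basis(np.array([5.0, 9.9]), knots=self.KNOTS)
        assert np.allclose(B[:, 1], 0.0)

    def test_linear_beyond_last_knot(self):
        x = np.array([30.0, 31.0, 32.0, 33.0, 34.0])
        B = srv.rcs_basis(x, knots=self.KNOTS)
        assert np.allclose(np.diff(B[:, 1], 2), 0.0, atol=1e-9)

    def test_hand_evaluated_truncated_power(self):
        t1, t2, t3 = self.KNOTS
        x = 12.7
        hand = (
            max(x - t1, 0) ** 3
            - max(x - t2, 0) ** 3 * (t3 - t1) / (t3 - t2)
            + max(x - t3, 0) ** 3 * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        B = srv.rcs_basis(np.array([x]), knots=self.KNOTS)
        assert B[0, 1] == pytest.approx(hand, rel=1e-12)
        assert B[0, 0] == x

    def test_default_knots_from_percentiles(self):
        rng = np.random.default_rng(2)
        x = rng.normal(12.7, 2.3, 5000)
        B = srv.rcs_basis(x, n_knots=3)
        assert B.shape == (5000, 2)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            srv.rcs_basis(np.array([1.0]), knots=(1.0, 1.0, 2.0))
        with pytest.raises(ValueError):
            srv.rcs_basis(np.array([1.0]), knots=(1.0, 2.0))


class TestSubgroups:
    def test_single_level_matches_pooled(self, survival_cohort):
        _, truths = survival_cohort
        ep, bands = pipeline.make_episodes(truths)
        ep["one"] = 1
        covs = ["sigma_i", "male", "age"] + bands
        pooled = srv.fit_cox(ep, covs)
        table = srv.run_subgroup_analyses(ep, covs, {"all": "one"}, exposure="sigma_i")
        assert len(table) == 1
        assert table["hr_per5"].iloc[0] == pytest.approx(
            np.exp(5 * pooled.params["sigma_i"]), rel=1e-9
        )

    def test_null_cohort_sex_strata_near_one(self):
        cfg = sv.GeneratorConfig(
            n_subjects=2500, seed=77, log_hr_per_5mmhg_sd=0.0, baseline_hazard_rate=0.04
        )
        truths, _ = sv.generate_cohort(cfg)
        truths["time"] = truths["time_composite"]
        truths["event"] = truths["event_composite"]
        ep, bands = pipeline.make_episodes(truths)
        covs = ["sigma_i", "male", "age"] + bands
        table = srv.run_subgroup_analyses(ep, covs, {"sex": "male"}, exposure="sigma_i")
        assert len(table) == 2
        for _, row in table.iterrows():
            se = (np.log(row["hr_hi"]) - np.log(row["hr_per5"])) / 1.96
            assert abs(np.log(row["hr_per5"])) < 3 * se

    def test_age_interaction_monotone_across_bands(self):
        # generator truth: per-5 effect declines from HR ~2.2 at age 50
        # to ~1.1 at age 80
        cfg = sv.GeneratorConfig(
            n_subjects=8000,
            seed=88,
            log_hr_per_5mmhg_sd=0.441,
            log_hr_per_5_age_slope=-0.231,
            baseline_hazard_rate=0.06,
        )
        truths, _ = sv.generate_cohort(cfg)
        truths["time"] = truths["time_composite"]
        truths["event"] = truths["event_composite"]
        ep, bands = pipeline.make_episodes(truths)
        covs = ["sigma_i", "male", "age"] + bands
        table = srv.run_subgroup_analyses(
            ep, covs, {"age_at_risk": "age_band"}, exposure="sigma_i"
        )
        table = table.set_index("level").loc[list(srv.AGE_BANDS)]
        hrs = table["hr_per5"].to_numpy()
        assert np.all(np.diff(hrs) < 0)

    def test_empty_stratum_skipped_with_warning(self, survival_cohort):
        _, truths = survival_cohort
        ep, bands = pipeline.make_episodes(truths.head(200))
        ep.loc[ep["male"] == 1, "event"] = 0
        with pytest.warns(UserWarning, match="no events"):
            table = srv.run_subgroup_analyses(
                ep, ["sigma_i", "age"] + bands, {"sex": "male"}, exposure="sigma_i"
            )
        assert set(table["level"]) == {0}
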