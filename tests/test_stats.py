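"""Model-agnostic battery: aggregation, ANOVA, contrasts, EFA, power."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from agtkit import stats as st
from agtkit.synthetic_cohort import (GroupSpec, default_group_specs,
                                     default_loading_matrix, draw_subjects,
                                     simulate_questionnaires)


def _table(cells, groups=None, ages=None, reps=5):
    idx = [f"s{i}" for i in range(len(cells))]
    df = pd.DataFrame(np.asarray(cells, dtype=float), index=idx)
    df.columns = pd.MultiIndex.from_product([[3, 6, 9, 12], [.2, .4, .6, .8]])
    meta = pd.DataFrame(index=df.index)
    if groups is not None:
        meta["group"] = groups
    if ages is not None:
        meta["age"] = ages
    return st.AcceptanceTable(cells=df, overall=df.mean(axis=1), meta=meta,
                              repetitions=reps)


class TestAggregation:
    def test_all_accepted(self, default_cohort):
        t = default_cohort.trials.copy()
        t["accepted"] = 1
        tab = st.aggregate_acceptance(t)
        assert (tab.cells == 1.0).all().all()
        assert (tab.overall == 1.0).all()
        assert tab.repetitions == 5

    def test_alternating_cells_are_two_or_three_fifths(self, default_cohort):
        t = default_cohort.trials.copy()
        t = t.sort_values(["participant_id", "reward_apples", "effort_prop"])
        t["accepted"] = np.tile([1, 0, 1, 0, 1], len(t) // 5)
        tab = st.aggregate_acceptance(t)
        assert set(np.round(tab.cells.to_numpy().ravel(), 6)) == {0.6}

    def test_overall_equals_equal_weight_cell_mean(self, default_cohort):
        tab = st.aggregate_acceptance(default_cohort.trials)
        np.testing.assert_allclose(tab.overall, tab.cells.mean(axis=1),
                                   atol=1e-12)

    def test_missing_cells_rejected(self, default_cohort):
        t = default_cohort.trials
        broken = t[~((t["participant_id"] == t["participant_id"].iloc[0])
                     & (t["reward_apples"] == 3))]
        with pytest.raises(st.StatsError):
            st.aggregate_acceptance(broken)


class TestArcsine:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4)])
    def test_known_values(self, p, expected):
        assert st.arcsine_transform(p) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(st.StatsError):
            st.arcsine_transform(1.2)

    def test_monotone_preserves_group_order(self):
        p = np.sort(np.random.default_rng(0).random(50))
        t = st.arcsine_transform(p)
        assert (np.diff(t) >= 0).all()


class TestRmAnova:
    def test_matches_pingouin_two_way_within(self):
        rng = np.random.default_rng(1)
        cells = rng.random((18, 16))
        tab = _table(cells)
        res = st.rm_anova(tab, between=None, covariate=None, transform=False)
        long = tab.cells.stack([0, 1], future_stack=True).reset_index()
        long.columns = ["subj", "reward", "effort", "y"]
        ora = pg.rm_anova(data=long, dv="y", within=["reward", "effort"],
                          subject="subj", detailed=True).set_index("Source")
        for mine, theirs in [("reward", "reward"), ("effort", "effort"),
                             ("reward:effort", "reward * effort")]:
            assert res.loc[mine, "F"] == pytest.approx(ora.loc[theirs, "F"],
                                                       rel=1e-6)
        for eff in ("reward", "effort"):
            assert res.loc[eff, "epsilon"] == pytest.approx(
                ora.loc[eff, "eps"], rel=1e-6)

    def test_matches_pingouin_mixed_design(self):
        rng = np.random.default_rng(2)
        cells = rng.random((24, 16))
        groups = ["A"] * 12 + ["B"] * 12
        tab = _table(cells, groups=groups)
        res = st.rm_anova(tab, between="group", covariate=None,
                          transform=False)
        collapsed = tab.cells.T.groupby(level=0).mean().T
        long = collapsed.stack().reset_index()
        long.columns = ["subj", "reward", "y"]
        long["group"] = long["subj"].map(dict(zip(tab.cells.index, groups)))
        ora = pg.mixed_anova(data=long, dv="y", within="reward",
                             subject="subj", between="group").set_index("Source")
        assert res.loc["reward", "F"] == pytest.approx(
            ora.loc["reward", "F"], rel=1e-6)
        assert res.loc["reward:group", "F"] == pytest.approx(
            ora.loc["Interaction", "F"], rel=1e-6)
        assert res.loc["group", "F"] == pytest.approx(
            ora.loc["group", "F"], rel=1e-6)

    def test_within_ss_matches_classical_cell_mean_oracle(self):
        """Six-subject toy: averaged-contrast F equals the classical
        subject x condition decomposition computed from cell means."""
        rng = np.random.default_rng(3)
        cells = rng.random((6, 16))
        tab = _table(cells)
        res = st.rm_anova(tab, between=None, covariate=None, transform=False)
        y = tab.cells.T.groupby(level=0).mean().T.to_numpy()  # collapse effort
        n, L = y.shape
        grand = y.mean()
        ss_a = n * ((y.mean(axis=0) - grand) ** 2).sum()
        resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + grand
        ss_axs = (resid ** 2).sum()
        f_classic = (ss_a / (L - 1)) / (ss_axs / ((L - 1) * (n - 1)))
        assert res.loc["reward", "F"] == pytest.approx(f_classic, rel=1e-8)

    def test_flat_cell_means_give_null_within_effects(self):
        # constant cell means + tiny noise: no reward/effort structure
        flat = np.full((8, 16), 0.5) + np.random.default_rng(0).normal(
            0, 1e-3, (8, 16))
        res = st.rm_anova(_table(flat), between=None, covariate=None,
                          transform=False)
        assert (res.loc[["reward", "effort", "reward:effort"], "p"] > 0.2).all()

    def test_two_level_factors_have_epsilon_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((10, 4)),
                          index=[f"s{i}" for i in range(10)])
        df.columns = pd.MultiIndex.from_product([[3, 12], [.2, .8]])
        tab = st.AcceptanceTable(cells=df, overall=df.mean(axis=1),
                                 meta=pd.DataFrame(index=df.index),
                                 repetitions=5)
        res = st.rm_anova(tab, between=None, covariate=None, transform=False)
        assert (res.loc[["reward", "effort"], "epsilon"] == 1.0).all()
        assert not res["sphericity_violated"].any()

    def test_deficient_group_named_in_error(self):
        rng = np.random.default_rng(5)
        tab = _table(rng.random((5, 16)), groups=["A"] * 4 + ["B"])
        with pytest.raises(st.StatsError, match="B"):
            st.rm_anova(tab, between="group", covariate=None)

    def test_age_covariate_changes_between_df(self):
        rng = np.random.default_rng(6)
        groups = ["CTR", "REL", "REM", "MDD"] * 45
        tab = _table(rng.random((180, 16)), groups=groups,
                     ages=rng.normal(35, 10, 180))
        res = st.rm_anova(tab, between="group", covariate="age")
        assert res.loc["group", "df1"] == 3
        assert res.loc["group", "df2"] == 175  # 180 - 4 - 1


class TestPlannedContrasts:
    def test_equal_means_give_zero_d(self):
        rng = np.random.default_rng(0)
        base = rng.random(40)
        vals = pd.Series(np.concatenate([base, base, base, base]))
        groups = pd.Series(["CTR"] * 40 + ["REL"] * 40 + ["REM"] * 40
                           + ["MDD"] * 40)
        for c in st.planned_contrasts(vals, groups):
            assert c.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_one_pooled_sd_gap_gives_d_of_one(self):
        a = np.array([1.0, 2.0, 3.0] * 10)
        b = a + a.std(ddof=1)
        vals = pd.Series(np.concatenate([b, a]))
        groups = pd.Series(["MDD"] * 30 + ["CTR"] * 30)
        res = st.planned_contrasts(vals, groups, contrasts=(
            ("MDD vs CTR", ("MDD",), ("CTR",)),))
        assert res[0].cohens_d == pytest.approx(1.0)

    def test_recovers_generating_k_gap_of_039(self):
        """Contrast 1 on the true acceptance-bias values approaches the
        generating effect size at large n."""
        specs = default_group_specs(age_effect_on_k=0.0)
        vals, groups = [], []
        for i, (g, spec) in enumerate(specs.items()):
            subs = draw_subjects(spec, 2000, seed=50 + i)
            vals += [s.params.K for s in subs]
            groups += [g] * 2000
        res = st.planned_contrasts(pd.Series(vals), pd.Series(groups))
        d1 = next(c for c in res if c.label == "MDD+REM vs REL+CTR")
        assert abs(d1.cohens_d) == pytest.approx(0.39, abs=0.05)

    def test_empty_pool_rejected(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        groups = pd.Series(["CTR", "REL"], index=["a", "b"])
        with pytest.raises(st.StatsError):
            st.planned_contrasts(vals, groups)


class TestAncova:
    def test_identical_group_distributions_give_zero_f(self):
        block = [1.0, 2.0, 3.0, 4.0, 5.0]
        est = pd.DataFrame({"K": block * 4,
                            "group": np.repeat(["A", "B", "C", "D"], 5)})
        rep = st.ancova_parameters(est)
        assert rep.omnibus.loc[0, "F"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_parameter_skipped(self):
        rng = np.random.default_rng(0)
        est = pd.DataFrame({"K": rng.normal(size=20), "LinE": -15.0,
                            "group": ["A", "B"] * 10})
        rep = st.ancova_parameters(est)
        assert "LinE" in rep.skipped
        assert set(rep.omnibus["parameter"]) == {"K"}

    def test_posthoc_holm_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        est = pd.DataFrame({
            "K": np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15),
                                 rng.normal(2, 1, 15)]),
            "group": np.repeat(["A", "B", "C"], 15)})
        rep = st.ancova_parameters(est, age=pd.Series(rng.normal(35, 8, 45)))
        assert (rep.posthoc["p_holm"] >= rep.posthoc["p"] - 1e-12).all()

    def test_single_group_rejected(self):
        est = pd.DataFrame({"K": [1.0, 2.0], "group": ["A", "A"]})
        with pytest.raises(st.StatsError):
            st.ancova_parameters(est)


@pytest.fixture(scope="module")
def questionnaire_sample():
    subs = draw_subjects(GroupSpec(label="X"), 400, seed=14)
    return pd.DataFrame([simulate_questionnaires(s, seed=500 + i)
                         for i, s in enumerate(subs)])


class TestEfa:
    def test_recovers_generating_structure(self, questionnaire_sample):
        sol = st.efa(questionnaire_sample, n_factors=4)
        gen = default_loading_matrix()

        def congruence(a, b):
            return abs(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))

        for f in gen.columns:
            best = max(congruence(gen[f].to_numpy(), sol.loadings[c].to_numpy())
                       for c in sol.loadings.columns)
            assert best >= 0.95

    def test_orthogonal_generator_yields_small_factor_correlations(
            self, questionnaire_sample):
        sol = st.efa(questionnaire_sample, n_factors=4)
        off = sol.phi.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.25

    def test_rank_one_data_single_factor(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=300)
        X = pd.DataFrame(np.outer(latent, [0.9, 0.8, 0.7, 0.85])
                         + rng.normal(0, 0.05, (300, 4)))
        sol = st.efa(X, n_factors=1, rotation="varimax")
        assert (sol.loadings.abs() > 0.9).all().all()
        assert (sol.uniquenesses < 0.1).all()

    def test_small_sample_warns(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 12)))
        with pytest.warns(UserWarning, match="fewer than"):
            st.efa(X, n_factors=2)


class TestCorrelations:
    def test_identical_series_give_unit_r(self):
        x = pd.DataFrame({"K": np.arange(10.0)}, index=range(10))
        s = pd.DataFrame({"F1": np.arange(10.0)}, index=range(10))
        out = st.correlate_params_factors(x, s)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"K": rng.normal(size=30)})
        s = pd.DataFrame({"F1": rng.normal(size=30)})
        r0 = st.correlate_params_factors(x, s)["r"].iloc[0]
        r1 = st.correlate_params_factors(x * 3.0 + 7.0, s * -2.0)["r"].iloc[0]
        assert abs(r1) == pytest.approx(abs(r0))

    def test_null_rejection_rate_matches_alpha(self):
        """|r| > 0.24 should occur in about 5% of null samples at n = 67."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = pd.DataFrame({"K": rng.normal(size=67)})
            s = pd.DataFrame({"F1": rng.normal(size=67)})
            if abs(st.correlate_params_factors(x, s)["r"].iloc[0]) > 0.2404:
                hits += 1
        assert 0.01 <= hits / n_rep <= 0.10

    def test_too_few_subjects_rejected(self):
        x = pd.DataFrame({"K": [1.0, 2.0]})
        s = pd.DataFrame({"F1": [1.0, 2.0]})
        with pytest.raises(st.StatsError):
            st.correlate_params_factors(x, s)


class TestPower:
    def test_study_design_is_adequately_powered(self):
        assert st.anova_power(180, 4, 0.25, 0.05) >= 0.80

    def test_null_effect_gives_alpha(self):
        assert st.anova_power(180, 4, 1e-9, 0.05) == pytest.approx(0.05,
                                                                   abs=1e-6)

    def test_power_increases_with_n(self):
        powers = [st.anova_power(n, 4, 0.25) for n in (40, 80, 160, 320)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(st.StatsError):
            st.anova_power(3, 4, 0.25)
        with pytest.raises(st.StatsError):
            st.anova_power(100, 4, -0.1)


class TestExclusion:
    def test_all_pass_is_identity(self):
        df = pd.DataFrame({"participant_id": ["a", "b"],
                           "practice_pass_high": [True, True]})
        kept, log = st.exclusion_filter(df)
        assert len(kept) == 2 and log.empty

    def test_finds_all_flagged_miscalibrations(self):
        from agtkit.synthetic_cohort import generate_cohort
        cohort = generate_cohort([GroupSpec(label="A"), GroupSpec(label="B")],
                                 [20, 20], seed=0, n_miscalibrated=14)
        kept, log = st.exclusion_filter(cohort.participants)
        assert len(log) == 14
        assert len(kept) == 26

    def test_idempotent(self):
        df = pd.DataFrame({"participant_id": list("abcd"),
                           "practice_pass_high": [True, False, True, False]})
        once, _ = st.exclusion_filter(df)
        twice, log2 = st.exclusion_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.empty
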