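import numpy as np
import pytest
from scipy import stats as sps

from cdfd.errors import ParameterError
from cdfd.modulation import (
    habituation_split,
    mixed_anova,
    paired_bin_t,
    population_profile,
    proportion_chisq,
    two_within_anova,
    window_mean_test,
)
from tests.conftest import make_zprofile


def brute_force_two_within(y):
    """Loop-based full SS decomposition for the context x phase design."""
    n, a, b = y.shape
    grand = y.mean()
    ma = [y[:, i, :].mean() for i in range(a)]
    mb = [y[:, :, j].mean() for j in range(b)]
    ms = [y[s].mean() for s in range(n)]
    out = {}
    ss_a = n * b * sum((m - grand) ** 2 for m in ma)
    ss_as = b * sum(
        (y[s, i, :].mean() - ms[s] - ma[i] + grand) ** 2 for s in range(n) for i in range(a)
    )
    out["A"] = ((ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1))), ss_a)
    ss_b = n * a * sum((m - grand) ** 2 for m in mb)
    ss_bs = a * sum(
        (y[s, :, j].mean() - ms[s] - mb[j] + grand) ** 2 for s in range(n) for j in range(b)
    )
    out["B"] = ((ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1))), ss_b)
    ss_ab = n * sum(
        (y[:, i, j].mean() - ma[i] - mb[j] + grand) ** 2 for i in range(a) for j in range(b)
    )
    ss_abs = sum(
        (
            y[s, i, j]
            - y[s, i, :].mean()
            - y[s, :, j].mean()
            - y[:, i, j].mean()
            + ms[s]
            + ma[i]
            + mb[j]
            - grand
        )
        ** 2
        for s in range(n)
        for i in range(a)
        for j in range(b)
    )
    out["AB"] = (
        (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1))),
        ss_ab,
    )
    return out


class TestPairedBinT:
    def test_identical_profiles(self):
        z = np.linspace(-1, 4, 30)
        res = paired_bin_t(z, z)
        assert res.t == 0.0 and not res.significant and res.direction == "none"

    def test_alternating_difference_hand_oracle(self):
        zB = np.zeros(30)
        zA = np.tile([1.0, 0.0], 15)
        res = paired_bin_t(zA, zB)
        sd = np.sqrt(15 * 0.25 * 2 / 29)
        assert res.t == pytest.approx(0.5 / (sd / np.sqrt(30)), abs=1e-9)
        assert res.t == pytest.approx(5.385, abs=1e-3)
        assert res.significant and res.direction == "positive"
        assert res.raw_sum == pytest.approx(15.0)
        assert res.df == 29

    def test_constant_difference_degenerate(self):
        res = paired_bin_t(np.full(30, 0.7), np.zeros(30))
        assert res.degenerate and res.direction == "positive" and np.isnan(res.t)
        assert not res.significant

    def test_matches_textbook_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 40)
            a, b = rng.normal(size=n), rng.normal(size=n)
            res = paired_bin_t(a, b)
            t_ref, p_ref = sps.ttest_rel(a, b)
            assert res.t == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    @pytest.mark.parametrize("a,b", [([1.0], [2.0]), ([1, 2], [1, 2, 3]), ([np.nan, 1], [0, 0])])
    def test_invalid_inputs(self, a, b):
        with pytest.raises(ParameterError):
            paired_bin_t(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


class TestProportionChisq:
    def test_symmetric_counts_give_zero(self):
        chi2, df, p = proportion_chisq(7, 7, 24)
        assert chi2 == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_expected_count_oracle(self):
        # table [[6,6],[2,10]]: expected all-cells from margins -> chi2 = 3
        chi2, _, _ = proportion_chisq(6, 2, 12)
        assert chi2 == pytest.approx(3.0, abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            n_pos = int(rng.integers(0, n + 1))
            n_neg = int(rng.integers(0, n - n_pos + 1))
            obs = np.array([[n_pos, n - n_pos], [n_neg, n - n_neg]])
            if (obs.sum(0) == 0).any():
                continue
            chi2, df, p = proportion_chisq(n_pos, n_neg, n)
            ref = sps.chi2_contingency(obs, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ParameterError):
            proportion_chisq(1, 1, 0)
        with pytest.raises(ParameterError):
            proportion_chisq(10, 5, 12)
        with pytest.raises(ParameterError):
            proportion_chisq(0, 0, 10)  # empty significant margin


class TestWindowMeanTest:
    def _profiles(self, means):
        return {f"u{i}": make_zprofile([m], 1.0, (0.0, 1.0)) for i, m in enumerate(means)}

    def test_identical_profiles_t_zero(self):
        pa = self._profiles([1.0, 2.0, 3.0])
        pb = self._profiles([1.0, 2.0, 3.0])
        res = window_mean_test(pa, pb, (0.0, 1.0))
        assert res["t"] == 0.0 and not res["significant"] and not res["degenerate"]

    def test_hand_oracle(self):
        res = window_mean_test(
            self._profiles([2.0, 3.0, 5.0]), self._profiles([1.0, 2.0, 3.0]), (0.0, 1.0)
        )
        assert res["t"] == pytest.approx(4.0, abs=1e-12)
        assert res["df"] == 2 and res["n_units"] == 3

    def test_constant_difference_degenerate(self):
        res = window_mean_test(
            self._profiles([2.0, 3.0]), self._profiles([1.0, 2.0]), (0.0, 1.0)
        )
        assert res["degenerate"] and res["t"] is None

    def test_requires_matched_units_and_two_of_them(self):
        pa = self._profiles([1.0, 2.0])
        pb = {"u0": pa["u0"]}
        with pytest.raises(ParameterError):
            window_mean_test(pa, pb, (0.0, 1.0))
        with pytest.raises(ParameterError):
            window_mean_test({"u0": pa["u0"]}, {"u0": pa["u0"]}, (0.0, 1.0))


class TestPopulationProfile:
    def test_single_unit(self):
        z = make_zprofile([1.0, -2.0, 0.5])
        pop = population_profile({"u": z}, "A")
        np.testing.assert_allclose(pop.mean_z, z.z)
        assert np.all(np.isnan(pop.se_z)) and pop.n_units == 1

    def test_antisymmetric_pair_averages_to_zero(self):
        z = np.array([1.0, -2.0, 0.5])
        pop = population_profile(
            {"a": make_zprofile(z), "b": make_zprofile(-z)}, "A"
        )
        np.testing.assert_allclose(pop.mean_z, 0.0, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ParameterError):
            population_profile(
                {"a": make_zprofile([1.0, 2.0]), "b": make_zprofile([1.0, 2.0, 3.0])}, "A"
            )

    def test_null_population_mean_is_bounded(self, null_session):
        from tests.conftest import profiles_from

        profs = profiles_from(
            null_session, null_session.events, 1.0, (-20.0, 30.0), (-20.0, 0.0)
        )
        usable = {u: p for u, p in profs.items() if not p.degenerate}
        pop = population_profile(usable, "pooled")
        base = pop.mean_z[:20]
        assert np.max(np.abs(base)) < 1.0


class TestTwoWithinAnova:
    def test_identical_cells_flagged(self):
        table = two_within_anova(np.full((4, 2, 2), 3.0))
        assert table.effects["ss"].eq(0).all()
        assert table.effects["F"].isna().all() and table.notes

    def test_constructed_context_effect_matches_bruteforce(self):
        # 3 units, clear context effect, no phase effect, small unit jitter
        base = np.array([0.2, -0.1, 0.05])
        ctx_gain = np.array([1.0, 1.1, 0.95])  # subject-varying context response
        y = np.zeros((3, 2, 2))
        y[:, 0, :] = ctx_gain[:, None]
        y += base[:, None, None]
        y[:, :, 1] += np.array([0.01, -0.02, 0.01])[:, None]  # phase jitter, zero mean
        table = two_within_anova(y)
        ref = brute_force_two_within(y)
        assert table.effect("context")["F"] == pytest.approx(ref["A"][0], rel=1e-10)
        assert table.effect("context")["F"] > 100.0
        assert table.effect("phase")["ss"] == pytest.approx(0.0, abs=1e-12)
        assert table.effect("phase")["F"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_and_statsmodels_on_random_designs(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(17)
        for k in range(25):
            n, a, b = int(rng.integers(3, 8)), int(rng.integers(2, 4)), int(rng.integers(2, 4))
            y = rng.normal(size=(n, a, b))
            table = two_within_anova(y, ("A", "B"))
            ref = brute_force_two_within(y)
            for eff, key in (("A", "A"), ("B", "B"), ("A:B", "AB")):
                assert table.effect(eff)["F"] == pytest.approx(ref[key][0], abs=1e-10)
                assert table.effect(eff)["ss"] == pytest.approx(ref[key][1], abs=1e-10)
            if k < 5:  # independent library oracle on a few designs
                long = pd.DataFrame(
                    [
                        dict(subject=s, A=i, B=j, y=y[s, i, j])
                        for s in range(n)
                        for i in range(a)
                        for j in range(b)
                    ]
                )
                sm = AnovaRM(long, "y", "subject", within=["A", "B"]).fit().anova_table
                assert table.effect("A")["F"] == pytest.approx(sm.loc["A", "F Value"], abs=1e-8)
                assert table.effect("B")["F"] == pytest.approx(sm.loc["B", "F Value"], abs=1e-8)
                assert table.effect("A:B")["F"] == pytest.approx(sm.loc["A:B", "F Value"], abs=1e-8)

    def test_factor_swap_symmetry(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(5, 2, 2))
        t1 = two_within_anova(y)
        t2 = two_within_anova(y[:, ::-1, :])  # relabel context levels
        for eff in ("context", "phase", "context:phase"):
            assert t1.effect(eff)["F"] == pytest.approx(t2.effect(eff)["F"], abs=1e-12)


class TestMixedAnova:
    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(23)
        for _ in range(5):
            n, k = int(rng.integers(6, 12)), int(rng.integers(2, 4))
            y = rng.normal(size=(n, k))
            groups = np.array(["g1"] * (n // 2) + ["g2"] * (n - n // 2))
            table = mixed_anova(y, groups)
            long = pd.DataFrame(
                [
                    dict(subject=s, group=groups[s], w=j, y=y[s, j])
                    for s in range(n)
                    for j in range(k)
                ]
            )
            ref = pg.mixed_anova(
                data=long, dv="y", within="w", subject="subject", between="group"
            ).set_index("Source")
            assert table.effect("group")["F"] == pytest.approx(ref.loc["group", "F"], abs=1e-8)
            assert table.effect("within")["F"] == pytest.approx(ref.loc["w", "F"], abs=1e-8)
            assert table.effect("group:within")["F"] == pytest.approx(
                ref.loc["Interaction", "F"], abs=1e-8
            )


class TestHabituationSplit:
    def test_runs_and_reports_design_dfs(self, modulated_session):
        table = habituation_split(
            modulated_session.spike_trains, modulated_session.events, variant="sustained"
        )
        n = table.cell_means["unit_id"].nunique()
        assert table.effect("context")["df"] == 1
        assert table.effect("context")["df_error"] == n - 1
        assert len(table.cell_means) == 4 * n

    def test_context_swap_leaves_f_unchanged(self, modulated_session):
        events = modulated_session.events
        swapped = events.assign(context=events["context"].map({"A": "B", "B": "A"}))
        t1 = habituation_split(modulated_session.spike_trains, events, variant="sustained")
        t2 = habituation_split(modulated_session.spike_trains, swapped, variant="sustained")
        for eff in ("context", "phase", "context:phase"):
            assert t1.effect(eff)["F"] == pytest.approx(t2.effect(eff)["F"], abs=1e-9)

    def test_needs_six_trials_per_context(self, modulated_session):
        short = modulated_session.events[modulated_session.events["trial_index"] <= 4]
        with pytest.raises(ParameterError):
            habituation_split(modulated_session.spike_trains, short)
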