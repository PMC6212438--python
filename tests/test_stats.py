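"""Inferential toolbox: each procedure is checked against an independent
oracle (explicit sums of squares, Monte-Carlo studentized range, literal
step-up FDR, t-distribution degeneracies) and against frozen hand arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from orpanel import stats, synth, traceproc
from orpanel.errors import DataError, InsufficientDataError, ParameterError
from orpanel.synth import AffinityEntry, AffinityModel, Ces1dModel, NoiseParams


class TestOneWayAnova:
    def test_hand_computed_example(self):
        res = stats.one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.f == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(sps.f.sf(1.5, 1, 4), rel=1e-9)

    def test_constant_groups(self):
        res = stats.one_way_anova([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.f == 0.0
        assert res.p == 1.0

    def test_panel_design_degrees_of_freedom(self):
        groups = [np.random.default_rng(i).normal(size=3) for i in range(7)]
        res = stats.one_way_anova(groups)
        assert (res.df_between, res.df_within) == (6, 14)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        groups = [rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(2, 8))
                  for _ in range(k)]
        mine = stats.one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert mine.f == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientDataError):
            stats.one_way_anova([[1.0], [1.0, 2.0]])


class TestFCritical:
    def test_panel_threshold(self):
        assert round(stats.f_critical(6, 14, 0.05), 2) == 2.85

    def test_numeric_quantile(self):
        assert stats.f_critical(3, 10, 0.05) == pytest.approx(3.708, abs=5e-4)

    def test_normal_limit(self):
        assert stats.f_critical(1, 10 ** 6, 0.05) == pytest.approx(1.96 ** 2, abs=1e-2)

    def test_inverse_cdf_consistency(self):
        crit = stats.f_critical(6, 14, 0.05)
        assert sps.f.cdf(crit, 6, 14) == pytest.approx(0.95, abs=1e-8)

    @pytest.mark.parametrize("df1, df2, alpha", [(0, 5, 0.05), (3, 5, 0.0), (3, 5, 1.0)])
    def test_parameter_errors(self, df1, df2, alpha):
        with pytest.raises(ParameterError):
            stats.f_critical(df1, df2, alpha)

    def test_null_rejection_rate_matches_alpha(self):
        """P(F >= f_critical) = alpha under the null, by simulation."""
        rng = np.random.default_rng(99)
        n_sim, k, n = 10_000, 3, 3
        data = rng.normal(size=(n_sim, k, n))
        f = sps.f_oneway(*(data[:, i, :] for i in range(k)), axis=1).statistic
        crit = stats.f_critical(k - 1, k * (n - 1), 0.05)
        rate = np.mean(f >= crit)
        tol = 4 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < tol


def mc_studentized_range_p(q_obs, k, df, n_draws=1_000_000, seed=17):
    """Monte-Carlo oracle for P(Q_{k,df} >= q_obs)."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_draws, k))
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    q = (z.max(axis=1) - z.min(axis=1)) / s
    return float(np.mean(q >= q_obs))


class TestTukey:
    def test_identical_groups(self):
        res = stats.tukey_hsd([[1.0, 2.0, 3.0]] * 3)
        assert (res["p_adj"] > 0.999).all()
        assert np.allclose(res["mean_diff"], 0.0)

    def test_two_groups_reduce_to_pooled_t(self):
        a, b = [1.0, 2.0, 3.5], [2.5, 3.0, 4.5]
        res = stats.tukey_hsd([a, b])
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert res["p_adj"].iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_matches_monte_carlo_oracle(self):
        groups = [[1.0, 1.4, 0.9], [2.2, 2.0, 2.6], [1.1, 1.6, 1.3]]
        res = stats.tukey_hsd(groups, labels=["g0", "g1", "g2"])
        arrays = [np.asarray(g) for g in groups]
        df = sum(a.size for a in arrays) - len(arrays)
        msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
        for _, row in res.iterrows():
            q_obs = abs(row["mean_diff"]) / np.sqrt(msw / 3)
            p_mc = mc_studentized_range_p(q_obs, k=3, df=df)
            assert row["p_adj"] == pytest.approx(p_mc, abs=0.01)

    def test_symmetric_pair_table(self, matrix_pair):
        m, _ = matrix_pair
        counts = stats.differential_activation_counts(m)
        assert (counts.to_numpy() == counts.to_numpy().T).all()
        assert (counts.to_numpy().diagonal() == 0).all()
        assert counts.to_numpy().max() <= 31


class TestDifferentialActivation:
    def test_planted_single_discriminating_receptor(self):
        """OR1 responds only to odorant A: pairs with A count OR1, others don't."""
        from orpanel.core import Condition
        aff = AffinityModel({("OR1", "A"): AffinityEntry(1e-5, 6.0)})
        design = synth.PanelDesign(
            or_ids=("OR1", "OR2", "pCI"), control_id="pCI",
            odorant_ids=("A", "B", "C"),
            conditions=tuple(Condition(o, "vapor", 1e-2) for o in "ABC"),
        )
        run = synth.simulate_plate_run(design, aff, noise=NoiseParams(0, 0.01, 0),
                                       seed=8)
        m = traceproc.build_response_matrix(run)
        counts = stats.differential_activation_counts(m)
        assert counts.loc["A", "B"] >= 1
        assert counts.loc["A", "C"] >= 1
        assert counts.loc["B", "C"] == 0

    def test_null_panel_counts_near_zero(self):
        """With no signal, pair counts only reflect ~alpha-level false positives."""
        from orpanel.core import Condition
        design = synth.PanelDesign(
            or_ids=tuple(f"OR{i}" for i in range(10)) + ("pCI",), control_id="pCI",
            odorant_ids=("A", "B", "C"),
            conditions=tuple(Condition(o, "vapor", 1e-2) for o in "ABC"),
        )
        run = synth.simulate_plate_run(design, AffinityModel(), seed=21)
        counts = stats.differential_activation_counts(
            traceproc.build_response_matrix(run))
        # 10 receptors x 3 pairs, ANOVA-gated Tukey at 0.05: expect ~0-2 hits total
        assert counts.to_numpy().sum() / 2 <= 4

    def test_default_panel_every_pair_discriminated(self, matrix_pair):
        """Planted distinct codes: each analog pair separated by >= 1 receptor."""
        m, _ = matrix_pair
        counts = stats.differential_activation_counts(m)
        off_diag = counts.to_numpy()[~np.eye(len(counts), dtype=bool)]
        assert off_diag.min() >= 1


class TestDunnettOnset:
    def test_flat_null_no_onset(self):
        rng = np.random.default_rng(1)
        cycles = {c: 1 + 0.01 * rng.normal(size=3) for c in range(1, 9)}
        res = stats.dunnett_onset(cycles, baseline_cycle=1)
        assert res.onset_cycle is None

    def test_step_increase_detected_at_step(self):
        rng = np.random.default_rng(2)
        cycles = {c: (1.0 if c < 5 else 3.0) + 0.01 * rng.normal(size=3)
                  for c in range(1, 9)}
        res = stats.dunnett_onset(cycles, baseline_cycle=1)
        assert res.onset_cycle == 5
        assert res.anova.p < 0.05

    def test_negative_shift_is_not_an_onset(self):
        rng = np.random.default_rng(3)
        cycles = {c: (1.0 if c < 5 else 0.2) + 0.01 * rng.normal(size=3)
                  for c in range(1, 9)}
        res = stats.dunnett_onset(cycles, baseline_cycle=1)
        assert res.onset_cycle is None

    def test_single_comparison_degenerates_to_t_test(self):
        """With one non-baseline cycle, the adjusted p equals a pooled t-test p."""
        a = np.array([1.0, 1.2, 0.9, 1.1])
        b = np.array([1.8, 2.1, 1.7, 2.0])
        res = stats.dunnett_onset({1: a, 2: b}, baseline_cycle=1)
        t_p = sps.ttest_ind(b, a, equal_var=True).pvalue
        assert res.adjusted_p[2] == pytest.approx(t_p, abs=1e-3)
        assert res.onset_cycle == 2


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert stats.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(stats.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(stats.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=20)
        np.testing.assert_allclose(stats.bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=15),
           st.integers(min_value=0, max_value=14), st.floats(min_value=0, max_value=0.3))
    def test_monotone_in_raw_p(self, pvals, idx, bump):
        """Raising any raw p never lowers any adjusted p."""
        idx = idx % len(pvals)
        bumped = list(pvals)
        bumped[idx] = min(1.0, bumped[idx] + bump)
        assert (stats.bh_fdr(bumped) >= stats.bh_fdr(pvals) - 1e-12).all()

    def test_rank_preserving(self):
        p = np.array([0.001, 0.2, 0.04, 0.9])
        adj = stats.bh_fdr(p)
        assert (np.argsort(adj, kind="stable") == np.argsort(p, kind="stable")).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            stats.bh_fdr([0.5, 1.2])


@pytest.fixture(scope="module")
def ces1d_matrices():
    """Zero/low-noise enzyme experiment with one gainer and one loser."""
    from orpanel.core import Condition
    aff = AffinityModel({
        ("OR_gain", "Ester"): AffinityEntry(1e-5, 0.8),
        ("OR_gain", "Alcohol"): AffinityEntry(1e-5, 5.0),
        ("OR_lose", "Ester"): AffinityEntry(1e-5, 5.0),
        ("OR_flat", "Other"): AffinityEntry(1e-5, 5.0),
    })
    design = synth.PanelDesign(
        or_ids=("OR_gain", "OR_lose", "OR_flat", "pCI"), control_id="pCI",
        odorant_ids=("Ester", "Alcohol", "Other"),
        conditions=(Condition("Ester", "vapor", 1e-2),),
    )
    enzyme = Ces1dModel((("Ester", "Alcohol", 0.95),))
    noise = NoiseParams(0.0, 0.02, 0.0)
    without = synth.simulate_plate_run(design, aff, noise=noise, seed=31)
    with_enz = synth.simulate_plate_run(design, aff, noise=noise, ces1d=enzyme, seed=32)
    return (traceproc.build_response_matrix(without),
            traceproc.build_response_matrix(with_enz))


class TestCes1dCompare:
    def test_identical_matrices_null(self, matrix_pair):
        m, _ = matrix_pair
        res = stats.ces1d_compare(m, m)
        assert np.allclose(res["fold"].dropna(), 1.0)
        assert not res["significant"].any()

    def test_product_responder_gains_significantly(self, ces1d_matrices):
        without, with_enz = ces1d_matrices
        res = stats.ces1d_compare(without, with_enz).set_index("or_id")
        assert res.loc["OR_gain", "fold"] > 1.5
        assert res.loc["OR_gain", "significant"]
        assert res.loc["OR_gain", "direction"] == "up"

    def test_substrate_responder_suppressed(self, ces1d_matrices):
        without, with_enz = ces1d_matrices
        res = stats.ces1d_compare(without, with_enz).set_index("or_id")
        assert res.loc["OR_lose", "fold"] < 0.5
        assert res.loc["OR_lose", "significant"]
        assert res.loc["OR_lose", "direction"] == "down"

    def test_adjusted_p_not_below_raw(self, ces1d_matrices):
        without, with_enz = ces1d_matrices
        res = stats.ces1d_compare(without, with_enz)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = stats.regression_r2(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_computed_r2(self):
        res = stats.regression_r2([1, 2, 3], [1, 2, 2])
        assert res.r_squared == pytest.approx(0.75, abs=1e-9)

    def test_constant_y_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            res = stats.regression_r2([1, 2, 3], [5, 5, 5])
        assert res.r_squared == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(DataError):
            stats.regression_r2([2, 2, 2], [1, 2, 3])


class TestReproducibilityContrast:
    def test_identical_lists(self):
        t, p, *_ = stats.reproducibility_contrast([0.9, 0.95], [0.9, 0.95])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_frozen_pooled_t(self):
        # pooled: t = 0.675 / sqrt(((0.00125+0.005)/2) * (1/2+1/2)) = 12.0748
        t, p, mean_same, mean_diff = stats.reproducibility_contrast(
            [0.9, 0.95], [0.2, 0.3], equal_var=True)
        assert t == pytest.approx(12.0748, abs=1e-3)
        assert p < 0.01
        assert mean_same > mean_diff

    def test_generator_defaults_separate_same_from_different(self, matrix_pair):
        from itertools import combinations
        m1, m2 = matrix_pair
        w1, w2 = m1.means_wide(), m2.means_wide()
        same = [stats.regression_r2(w1[k], w2[k]).r_squared for k in w1.columns]
        diff = [stats.regression_r2(w1[a], w1[b]).r_squared
                for a, b in combinations(w1.columns, 2)]
        t, p, mean_same, mean_diff = stats.reproducibility_contrast(same, diff)
        assert mean_same > 0.91
        assert 0.1 < mean_diff < 0.9
        assert t > 0 and p < 0.05


class TestHillRecovery:
    def test_ec50_recovered_within_twofold_at_default_noise(self, affinity):
        """Simulated dose series re-fit recovers the generative EC50."""
        or_id, odorant = "Olfr145", "AC"
        entry = affinity.entry(or_id, odorant)
        assert entry is not None
        dilutions = tuple(np.logspace(-5, 0, 9))
        design = synth.analog_panel_design(odorants=(odorant,), dilutions=dilutions)
        run = synth.simulate_plate_run(design, affinity, seed=55)
        wide = traceproc.build_response_matrix(run).means_wide()
        concs = np.array([1e-2 * d for d in dilutions])
        keys = sorted(wide.columns, key=lambda c: float(c.split("|")[2]))
        responses = wide.loc[or_id, keys].to_numpy(dtype=float)
        ec50, _, _ = stats.fit_hill(concs, responses)
        assert entry.ec50 / 2 < ec50 < entry.ec50 * 2
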