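"""Factorial GLM, EMMs, Newman-Keuls/Bonferroni post-hocs, repeated measures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dimorph import stats_core, synthgen


def _balanced_2x2(cells, n=5, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (a, b), mu in cells.items():
        for _ in range(n):
            rows.append({"A": a, "B": b, "y": mu + (rng.normal(0, sd) if sd else 0.0)})
    return pd.DataFrame(rows)


class TestFactorialGlm:
    def test_additive_cells_have_zero_interaction(self):
        data = _balanced_2x2({("a1", "b1"): 10, ("a1", "b2"): 12,
                              ("a2", "b1"): 14, ("a2", "b2"): 16},
                             n=4, sd=0.5, seed=1)
        res = stats_core.factorial_glm(data, "y", ["A", "B"], interactions="full")
        # additive truth: interaction F small relative to huge main effects
        assert res.anova.loc["A:B", "F"] < 0.2 * res.anova.loc["A", "F"]
        # EMMs of a balanced design equal raw marginal means
        for f in ("A", "B"):
            raw = data.groupby(f)["y"].mean()
            emm = res.emmeans[f]["emm"]
            assert np.allclose(emm.sort_index(), raw.sort_index())

    def test_crossover_loads_interaction_only(self):
        data = _balanced_2x2({("a1", "b1"): 10, ("a1", "b2"): 12,
                              ("a2", "b1"): 12, ("a2", "b2"): 10}, n=3)
        res = stats_core.factorial_glm(data, "y", ["A", "B"], interactions="full")
        assert res.anova.loc["A", "F"] == pytest.approx(0.0, abs=1e-20)
        assert res.anova.loc["B", "F"] == pytest.approx(0.0, abs=1e-20)
        cells = res.emmeans["cell"]["emm"]
        assert cells.loc[[("a1", "b1")]].iloc[0] == pytest.approx(10.0)

    def test_matches_normal_equations_oracle_unbalanced(self, rng):
        """F-tests and EMMs agree with an explicit general-linear-hypothesis
        computation from the normal equations on an unbalanced dataset."""
        rows = []
        sizes = {("a1", "b1"): 4, ("a1", "b2"): 7, ("a2", "b1"): 5, ("a2", "b2"): 9}
        for (a, b), n in sizes.items():
            for _ in range(n):
                rows.append({"A": a, "B": b, "y": rng.normal()})
        data = pd.DataFrame(rows)
        res = stats_core.factorial_glm(data, "y", ["A", "B"], interactions="full")

        # oracle: build the same sum-to-zero design by hand and test L*beta = 0
        a = np.where(data["A"] == "a1", 1.0, -1.0)
        b = np.where(data["B"] == "b1", 1.0, -1.0)
        X = np.column_stack([np.ones(len(data)), a, b, a * b])
        y = data["y"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfr = len(y) - 4
        mse = resid @ resid / dfr
        XtXi = np.linalg.inv(X.T @ X)
        for term, col in [("A", 1), ("B", 2), ("A:B", 3)]:
            F = beta[col] ** 2 / (XtXi[col, col] * mse)
            assert res.anova.loc[term, "F"] == pytest.approx(F, abs=1e-10)
            assert res.anova.loc[term, "p"] == pytest.approx(
                sps.f.sf(F, 1, dfr), abs=1e-12)
        # cell EMMs = model predictions at each cell
        for (la, lb), want in [(("a1", "b1"), [1, 1, 1, 1]),
                               (("a2", "b2"), [1, -1, -1, 1])]:
            pred = np.array(want, float) @ beta
            got = res.emmeans["cell"].loc[[(la, lb)], "emm"].iloc[0]
            assert got == pytest.approx(pred, abs=1e-10)
        assert res.mse == pytest.approx(mse, abs=1e-12)

    def test_invariant_to_factor_level_reordering(self, rng):
        data = _balanced_2x2({("a1", "b1"): 1, ("a1", "b2"): 3,
                              ("a2", "b1"): 2, ("a2", "b2"): 7}, n=4, sd=1, seed=3)
        r1 = stats_core.factorial_glm(data, "y", {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        r2 = stats_core.factorial_glm(data, "y", {"A": ["a2", "a1"], "B": ["b2", "b1"]})
        assert np.allclose(r1.anova["F"], r2.anova["F"])
        assert r1.emmeans["cell"]["emm"].sort_index().equals(
            r2.emmeans["cell"]["emm"].sort_index()) or np.allclose(
            r1.emmeans["cell"]["emm"].sort_index(),
            r2.emmeans["cell"]["emm"].sort_index())

    def test_empty_cell_with_interaction_raises(self):
        data = _balanced_2x2({("a1", "b1"): 1, ("a1", "b2"): 2, ("a2", "b1"): 3}, n=2)
        with pytest.raises(ValueError, match="empty design cells"):
            stats_core.factorial_glm(data, "y", ["A", "B"], interactions="full")

    def test_rank_deficient_design_names_aliased_columns(self):
        data = _balanced_2x2({("a1", "b1"): 1, ("a2", "b2"): 2}, n=3)
        data["C"] = data["A"]  # perfectly aliased factor
        with pytest.raises(Exception, match="aliased"):
            stats_core.factorial_glm(data, "y", ["A", "C"], interactions="none")


class TestNewmanKeuls:
    def test_equal_means_no_significant_pairs(self):
        data = _balanced_2x2({("a1", "b1"): 5, ("a1", "b2"): 5,
                              ("a2", "b1"): 5, ("a2", "b2"): 5}, n=4, sd=1, seed=2)
        res = stats_core.factorial_glm(data, "y", ["A", "B"])
        # tiny sampling differences only; with equal true means expect no calls
        snk = stats_core.newman_keuls(res, alpha=0.001)
        assert not snk["significant"].any()

    def test_two_groups_reduce_to_pooled_t(self, rng):
        rows = [{"G": g, "y": rng.normal(loc={"g1": 0, "g2": 1.2}[g])}
                for g in ["g1"] * 8 + ["g2"] * 8]
        data = pd.DataFrame(rows)
        res = stats_core.factorial_glm(data, "y", ["G"], interactions="none")
        snk = stats_core.newman_keuls(res, term="G", alpha=0.05)
        t, p = sps.ttest_ind(data.query("G=='g2'")["y"], data.query("G=='g1'")["y"])
        # q = t * sqrt(2); SNK p for span 2 equals the two-sample pooled t p
        assert snk.loc[0, "q"] == pytest.approx(abs(t) * np.sqrt(2), abs=1e-10)
        assert snk.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_hand_stepped_oracle_four_groups(self):
        """Match a manual SNK stepping with studentized-range critical values
        (q_0.05 for df=20: 2.95, 3.58, 3.96 at r=2,3,4 from published tables)."""
        # middle three means close together so a non-significant span
        # exercises the blocking rule
        means = {"g1": 10.0, "g2": 10.3, "g3": 10.6, "g4": 13.5}
        rows = []
        rng = np.random.default_rng(5)
        for g, mu in means.items():
            vals = rng.normal(0, 1, 6)
            vals = (vals - vals.mean()) / vals.std(ddof=1)  # exact mean/sd
            for v in vals * 1.0 + mu:
                rows.append({"G": g, "y": v})
        data = pd.DataFrame(rows)
        res = stats_core.factorial_glm(data, "y", ["G"], interactions="none")
        assert res.df_resid == 20
        assert res.mse == pytest.approx(1.0)
        snk = stats_core.newman_keuls(res, term="G", alpha=0.05)
        se = np.sqrt(1.0 / 6)
        qcrit = {2: 2.95, 3: 3.58, 4: 3.96}
        # manual stepping: test widest span first, block inside non-significant
        expected = {}
        nonsig = []
        order = sorted(means, key=means.get)
        m = [means[g] for g in order]
        for r in range(4, 1, -1):
            for i in range(0, 4 - r + 1):
                j = i + r - 1
                pair = (order[i], order[j])
                if any(a <= i and j <= b for a, b in nonsig):
                    expected[pair] = False
                    continue
                q = (m[j] - m[i]) / se
                sig = q > qcrit[r]
                expected[pair] = sig
                if not sig:
                    nonsig.append((i, j))
        got = {(row.level_1, row.level_2): row.significant
               for row in snk.itertuples()}
        assert got == expected

    def test_snk_blocking_consistent_with_bonferroni(self, rng):
        """A pair blocked inside a non-significant SNK span is never one that
        Bonferroni (same data, all pairs) declares significant."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            data = pd.DataFrame(
                [{"G": f"g{k}", "y": r.normal(0.3 * k, 1)}
                 for k in range(4) for _ in range(6)])
            res = stats_core.factorial_glm(data, "y", ["G"], interactions="none")
            snk = stats_core.newman_keuls(res, term="G")
            bon = stats_core.bonferroni_pairs(res, term="G")
            bon_sig = {frozenset((a, b)) for a, b, s in
                       zip(bon["level_1"], bon["level_2"], bon["significant"]) if s}
            blocked = {frozenset((a, b)) for a, b, bl in
                       zip(snk["level_1"], snk["level_2"], snk["blocked"]) if bl}
            assert not (blocked & bon_sig)


class TestBonferroni:
    def test_adjustment_arithmetic(self):
        data = pd.DataFrame(
            [{"G": g, "y": v} for g, vals in
             [("g1", [1.0, 2.0, 3.0]), ("g2", [2.0, 3.0, 4.0]),
              ("g3", [4.0, 5.0, 6.0]), ("g4", [0.0, 1.0, 2.0])]
             for v in vals])
        res = stats_core.factorial_glm(data, "y", ["G"], interactions="none")
        one = stats_core.bonferroni_pairs(res, pairs=[("g1", "g2")], term="G")
        assert one.loc[0, "p_adj"] == pytest.approx(one.loc[0, "p"])
        four = stats_core.bonferroni_pairs(
            res, pairs=[("g1", "g2"), ("g1", "g3"), ("g1", "g4"), ("g2", "g3")],
            term="G")
        assert np.allclose(four["p_adj"], np.minimum(1.0, four["p"] * 4))
        # monotone in raw p
        assert (four.sort_values("p")["p_adj"].diff().dropna() >= -1e-15).all()


class TestRepeatedMeasures:
    @staticmethod
    def _longitudinal(group_sizes, n_times, seed=0, group_shift=0.0, time_slope=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        sid = 0
        for g, n in enumerate(group_sizes):
            for _ in range(n):
                sid += 1
                u = rng.normal(0, 1)
                for t in range(n_times):
                    rows.append({"subject": f"s{sid:03d}", "group": f"g{g+1}",
                                 "time": t,
                                 "y": u + g * group_shift + t * time_slope
                                 + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_df_bookkeeping_matches_study_structure(self):
        """4 groups, 7 weekly time points, 58 subjects: the classic growth-curve
        layout yields time df (6, 324), interaction df (18, 324), group df (3, 54)."""
        data = self._longitudinal([15, 15, 14, 14], 7, time_slope=0.3)
        res = stats_core.repeated_measures_glm(data, "y", "subject", "time", "group")
        assert (res.loc["time", "df_num"], res.loc["time", "df_den"]) == (6, 324)
        assert (res.loc["time:group", "df_num"], res.loc["time:group", "df_den"]) == (18, 324)
        assert (res.loc["group", "df_num"], res.loc["group", "df_den"]) == (3, 54)

    def test_matches_pingouin_mixed_anova(self):
        pingouin = pytest.importorskip("pingouin")
        data = self._longitudinal([8, 8, 8], 4, seed=3, group_shift=0.5,
                                  time_slope=0.2)
        res = stats_core.repeated_measures_glm(data, "y", "subject", "time", "group")
        ref = pingouin.mixed_anova(data, dv="y", within="time", subject="subject",
                                   between="group").set_index("Source")
        assert res.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert res.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert res.loc["time:group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)
        assert res.loc["group", "p"] == pytest.approx(ref.loc["group", "p_unc"], abs=1e-10)

    def test_single_time_point_reduces_to_factorial_glm(self):
        data = self._longitudinal([6, 6], 1, seed=4, group_shift=1.0)
        res = stats_core.repeated_measures_glm(data, "y", "subject", "time", "group")
        glm = stats_core.factorial_glm(data, "y", ["group"], interactions="none")
        assert res.loc["group", "F"] == pytest.approx(glm.anova.loc["group", "F"])

    def test_null_p_uniform_across_seeds(self):
        """Without group or time effects, every term's p-values look uniform."""
        ps = {"group": [], "time": [], "time:group": []}
        for seed in range(120):
            data = self._longitudinal([5, 5], 3, seed=seed)
            res = stats_core.repeated_measures_glm(data, "y", "subject", "time", "group")
            for term in ps:
                ps[term].append(res.loc[term, "p"])
        for term, vals in ps.items():
            assert sps.kstest(vals, "uniform").pvalue > 0.01, term


def test_behavior_crossover_power():
    """A +/-1 SD Sex x Diet crossover at n=15/cell is detected (p<0.05)
    in at least 80% of simulated experiments."""
    cells = {("M", "LPD"): -1.0, ("M", "CTRL"): 1.0,
             ("F", "LPD"): 1.0, ("F", "CTRL"): -1.0}
    hits = 0
    n_seeds = 60
    for seed in range(n_seeds):
        beh = synthgen.simulate_behavior(cells, sd=1.0, n_per_cell=15, seed=seed)
        res = stats_core.factorial_glm(beh, "response", ["sex", "diet"])
        hits += res.anova.loc["sex:diet", "p"] < 0.05
    assert hits / n_seeds >= 0.8
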