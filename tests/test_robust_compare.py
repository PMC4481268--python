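import networkx as nx
import numpy as np
import pytest

import iatkit as ik
from iatkit.robust_compare import ContrastResult, relative_effects


def balanced_design(rng, n_per_cell=25, a_shift=0.0, b_shift=0.0, cross=0.0):
    """2x2 layout; ``cross`` adds a crossing interaction."""
    vals, fa, fb = [], [], []
    for la, da in (("a1", -a_shift / 2), ("a2", a_shift / 2)):
        for lb, db in (("b1", -b_shift / 2), ("b2", b_shift / 2)):
            sign = 1.0 if (la == "a2") == (lb == "b2") else -1.0
            vals.append(rng.standard_normal(n_per_cell) + da + db + sign * cross / 2)
            fa += [la] * n_per_cell
            fb += [lb] * n_per_cell
    return np.concatenate(vals), np.array(fa), np.array(fb)


class TestRelativeEffects:
    def test_weighted_mean_is_half(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2, 1, 200)
        groups = rng.choice(list("abcd"), 200)
        rel = relative_effects(values, groups)
        counts = np.array([(groups == g).sum() for g in rel.index])
        assert float((rel.to_numpy() * counts).sum() / 200) == pytest.approx(0.5)

    def test_stochastically_larger_group_above_half(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.standard_normal(100), rng.standard_normal(100) + 2]
        )
        groups = np.repeat(["lo", "hi"], 100)
        rel = relative_effects(values, groups)
        assert rel["hi"] > 0.7 > 0.3 > rel["lo"]


class TestBdmTwoWay:
    def test_cell_relative_effects_weighted_mean_half(self):
        rng = np.random.default_rng(2)
        vals, fa, fb = balanced_design(rng, a_shift=1.0)
        res = ik.bdm_two_way(vals, fa, fb)["factorA"]
        assert res.relative_effects.to_numpy().mean() == pytest.approx(0.5)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            vals, fa, fb = balanced_design(rng, n_per_cell=50, a_shift=3.0)
            res = ik.bdm_two_way(vals, fa, fb)
            if res["factorA"].p < 0.001:
                hits += 1
        assert hits == 20

    def test_factor_exchange_symmetry(self):
        rng = np.random.default_rng(4)
        vals, fa, fb = balanced_design(rng, a_shift=0.8, b_shift=0.3)
        res1 = ik.bdm_two_way(vals, fa, fb)
        res2 = ik.bdm_two_way(vals, fb, fa)
        assert res1["factorA"].statistic == pytest.approx(res2["factorB"].statistic)
        assert res1["interaction"].p == pytest.approx(res2["interaction"].p)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        vals, fa, fb = balanced_design(rng, a_shift=0.7)
        r1 = ik.bdm_two_way(vals, fa, fb)
        r2 = ik.bdm_two_way(np.exp(vals), fa, fb)
        for eff in ("factorA", "factorB", "interaction"):
            assert r1[eff].statistic == pytest.approx(r2[eff].statistic)
            assert r1[eff].df1 == pytest.approx(r2[eff].df1)

    def test_fractional_dfs_reported(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal(120)
        fa = rng.choice(list("abc"), 120)
        fb = rng.choice(["x", "y"], 120)
        res = ik.bdm_two_way(vals, fa, fb)["factorA"]
        assert 1.0 < res.df1 < 2.0 + 1e-9  # Box approximation is fractional
        assert res.df2 > 10

    def test_empty_cell_raises_naming_cell(self):
        vals = np.arange(30.0)
        fa = np.repeat(["a", "b"], 15)
        fb = np.array(["x"] * 15 + ["x"] * 15)
        fb[:15] = "y"
        # cell (a, x) and (b, y) empty
        with pytest.raises(ValueError, match="empty cell"):
            ik.bdm_two_way(vals, fa, fb)

    def test_constant_values_flagged_degenerate(self):
        vals = np.ones(40)
        fa = np.repeat(["a", "b"], 20)
        fb = np.tile(np.repeat(["x", "y"], 10), 2)
        res = ik.bdm_two_way(vals, fa, fb)
        assert all(r.degenerate for r in res.values())

    def test_eta_p2_conversion(self):
        rng = np.random.default_rng(7)
        vals, fa, fb = balanced_design(rng, a_shift=1.0)
        res = ik.bdm_two_way(vals, fa, fb)["factorA"]
        expected = res.df1 * res.statistic / (res.df1 * res.statistic + res.df2)
        assert res.eta_p2 == pytest.approx(expected)


class TestTukeyContrasts:
    def test_identical_samples_not_significant(self):
        x = np.tile(np.arange(20.0), 2)
        groups = np.repeat(["a", "b"], 20)
        (c,) = ik.tukey_relative_contrasts(x, groups, rng=0)
        assert c.effect == pytest.approx(0.0)
        assert not c.significant

    def test_complete_separation_significant(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.uniform(0, 1, 40), rng.uniform(2, 3, 40)])
        groups = np.repeat(["lo", "hi"], 40)
        (c,) = ik.tukey_relative_contrasts(x, groups, rng=0)
        assert c.significant
        assert abs(c.effect) == pytest.approx(0.5, abs=1e-9)  # boundary

    def test_stochastic_ordering_gives_transitive_chain(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.standard_normal(60) + shift for shift in (0.0, 1.2, 2.4)]
        )
        groups = np.repeat(["g0", "g1", "g2"], 60)
        contrasts = ik.tukey_relative_contrasts(x, groups, rng=0)
        assert all(c.significant for c in contrasts)
        winners = {(c.winner(), c.loser()) for c in contrasts}
        assert winners == {("g1", "g0"), ("g2", "g0"), ("g2", "g1")}

    def test_antisymmetry_of_relative_effect_difference(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(50)
        groups = np.repeat(["a", "b"], 25)
        (c,) = ik.tukey_relative_contrasts(x, groups, rng=0)
        rel = relative_effects(x, groups)
        assert c.effect == pytest.approx(rel["b"] - rel["a"])
        assert c.ci_low <= c.effect <= c.ci_high

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            ik.tukey_relative_contrasts([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPatelHoel:
    def test_null_covers_zero(self):
        rng = np.random.default_rng(11)
        vals, fa, fb = balanced_design(rng, n_per_cell=40, a_shift=1.0)
        res = ik.patel_hoel(vals, fa, fb)
        assert res.ci_low <= 0 <= res.ci_high

    def test_crossing_interaction_detected(self):
        rng = np.random.default_rng(12)
        vals, fa, fb = balanced_design(rng, n_per_cell=60, cross=2.5)
        res = ik.patel_hoel(vals, fa, fb)
        assert abs(res.delta) > 0.3
        assert res.p < 0.01
        assert not (res.ci_low <= 0 <= res.ci_high)

    def test_exchanging_b_levels_negates_delta(self):
        rng = np.random.default_rng(13)
        vals, fa, fb = balanced_design(rng, n_per_cell=30, cross=1.0)
        res = ik.patel_hoel(vals, fa, fb)
        swapped = np.where(fb == "b1", "b2", "b1")
        res2 = ik.patel_hoel(vals, fa, swapped)
        assert res2.delta == pytest.approx(-res.delta)

    def test_requires_2x2(self):
        vals = np.arange(30.0)
        with pytest.raises(ValueError, match="2 levels"):
            ik.patel_hoel(vals, np.repeat(list("abc"), 10), np.tile(["x", "y"], 15))

    def test_small_cell_rejected(self):
        vals = np.arange(7.0)
        fa = np.array(["a", "a", "b", "b", "a", "b", "a"])
        fb = np.array(["x", "x", "x", "x", "y", "y", "y"])
        with pytest.raises(ValueError, match="< 2"):
            ik.patel_hoel(vals, fa, fb)


def _contrast(i, j, effect, significant=True):
    return ContrastResult(
        group_i=i, group_j=j, effect=effect, se=0.01,
        ci_low=effect - 0.02 if not significant else effect - 0.005,
        ci_high=effect + 0.02 if not significant else effect + 0.005,
        p=0.001 if significant else 0.5, significant=significant,
    )


class TestTGraph:
    def test_transitive_edge_omitted(self):
        contrasts = [
            _contrast("Y", "X", 0.3),
            _contrast("Z", "Y", 0.3),
            _contrast("Z", "X", 0.6),
        ]
        tg = ik.build_tgraph(contrasts)
        assert set(tg.edges) == {("X", "Y"), ("Y", "Z")}

    def test_reachability_preserved(self):
        rng = np.random.default_rng(14)
        x = np.concatenate(
            [rng.standard_normal(50) + s for s in (0.0, 1.0, 2.0, 3.0)]
        )
        groups = np.repeat(["g0", "g1", "g2", "g3"], 50)
        contrasts = ik.tukey_relative_contrasts(x, groups, rng=0)
        tg = ik.build_tgraph(contrasts)
        before = {(u, v) for u in tg.full_graph for v in
                  nx.descendants(tg.full_graph, u)}
        after = {(u, v) for u in tg.graph for v in nx.descendants(tg.graph, u)}
        assert before == after

    def test_no_significant_contrasts_edgeless(self):
        contrasts = [_contrast("A", "B", 0.05, significant=False)]
        tg = ik.build_tgraph(contrasts)
        assert tg.edges == []
        assert set(tg.nodes) == {"A", "B"}

    def test_cycle_raises(self):
        contrasts = [
            _contrast("B", "A", 0.3),   # B beats A
            _contrast("C", "B", 0.3),   # C beats B
            _contrast("C", "A", -0.3),  # A beats C -> cycle
        ]
        with pytest.raises(ValueError, match="cycle"):
            ik.build_tgraph(contrasts)

    def test_dot_and_json_exports(self):
        tg = ik.build_tgraph([_contrast("Y", "X", 0.4)])
        dot = tg.to_dot()
        assert '"X" -> "Y"' in dot
        assert "digraph" in dot
        assert '"X"' in tg.to_json()
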