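"""Adjacency, topological overlap, module detection and trait association."""

import numpy as np
import pandas as pd
import pytest

from mirnet.coexpr import (CoexpressionModule, NetworkParams, adjacency,
                           coexpression_pipeline, dendrogram_newick,
                           detect_modules, eigengene, filter_expressed,
                           merge_modules, module_kme, module_trait,
                           select_hubs, tom)
from mirnet.quant import ExpressionMatrix

from oracles import bf_tom


def make_em(vals, samples, units="FPKM"):
    return ExpressionMatrix(vals, samples, units)


class TestFilterExpressed:
    def test_rule_application(self, samples12):
        rows = {
            # >= 2 in 9/12 samples (75%) and SD 0.3: kept
            "keep": [2.0] * 9 + [0.5] * 3,
            "low_fraction": [2.0] * 7 + [0.0] * 5,   # 58% above threshold
            "constant": [5.0] * 12,                  # SD 0
        }
        vals = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=samples12.index)
        out = filter_expressed(make_em(vals, samples12),
                               NetworkParams(min_sd=0.25))
        assert list(out.values.index) == ["keep"]

    def test_designed_pass_fail_fixture(self, samples12, rng):
        passing = {f"p{i}": rng.uniform(3, 10, 12) for i in range(4)}
        failing = {f"f{i}": rng.uniform(0, 1.5, 12) for i in range(6)}
        vals = pd.DataFrame.from_dict({**passing, **failing}, orient="index",
                                      columns=samples12.index)
        out = filter_expressed(make_em(vals, samples12), NetworkParams())
        assert sorted(out.values.index) == sorted(passing)


class TestAdjacency:
    def test_identical_and_orthogonal_profiles(self, samples12):
        x = np.arange(12, dtype=float)
        y = np.tile([1.0, -1.0], 6) + 5
        vals = pd.DataFrame([x, x + 3, y], index=["a", "b", "c"],
                            columns=samples12.index)
        a = adjacency(vals, beta=9)
        assert a.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "c"] < 0.01
        assert np.all(np.diag(a.values) == 1.0)

    def test_soft_power_direct_value(self):
        # exact r = 0.5 pair: v = u + sqrt(3) w with w orthogonal to u
        u = np.array([1.0, -1.0, 1.0, -1.0])
        w = np.array([1.0, 1.0, -1.0, -1.0])
        v = u + np.sqrt(3.0) * w
        assert np.corrcoef(u, v)[0, 1] == pytest.approx(0.5)
        a = adjacency(pd.DataFrame([u, v], index=["u", "v"]), beta=9)
        assert a.loc["u", "v"] == pytest.approx(0.5 ** 9)  # 0.001953125


class TestTom:
    def test_two_node_closed_form(self):
        a = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        t = tom(a)
        assert t.loc["a", "b"] == pytest.approx(0.3)

    def test_three_node_complete_graph_is_all_ones(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                         columns=list("abc"))
        t = tom(a)
        np.testing.assert_allclose(t.values, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for n in (10, 30):
            r = rng.uniform(0, 1, size=(n, n))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            ids = [f"g{i}" for i in range(n)]
            t = tom(pd.DataFrame(a, index=ids, columns=ids))
            # the formula sums over u != i, j: zero the diagonal for the oracle
            a0 = a.copy()
            np.fill_diagonal(a0, 0.0)
            expected = np.array(bf_tom(a0))
            np.fill_diagonal(expected, 1.0)
            np.testing.assert_allclose(t.values, expected, atol=1e-12)
            assert np.allclose(t.values, t.values.T)
            assert t.values.min() >= 0 and t.values.max() <= 1 + 1e-12

    def test_asymmetric_input_rejected(self):
        a = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom(a)


class TestModules:
    def planted_tom(self, n_blocks=2, size=60, within=0.95, between=0.001):
        n = n_blocks * size
        a = np.full((n, n), between)
        for b in range(n_blocks):
            a[b * size:(b + 1) * size, b * size:(b + 1) * size] = within
        np.fill_diagonal(a, 1.0)
        ids = [f"g{i:03d}" for i in range(n)]
        return tom(pd.DataFrame(a, index=ids, columns=ids))

    def test_two_planted_blocks_give_two_modules(self):
        t = self.planted_tom()
        mods = detect_modules(t, NetworkParams(min_module_size=50))
        real = [m for m in mods if m.label != "grey"]
        assert len(real) == 2
        assert all(m.size == 60 for m in real)
        assert mods[-1].label == "grey" and mods[-1].size == 0

    def test_structureless_matrix_is_all_grey(self, rng):
        n = 80
        r = rng.uniform(0, 0.02, size=(n, n))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"g{i}" for i in range(n)]
        mods = detect_modules(tom(pd.DataFrame(a, index=ids, columns=ids)),
                              NetworkParams(min_module_size=50))
        assert [m.label for m in mods] == ["grey"]
        assert mods[0].size == n

    def test_fewer_entities_than_min_size_pool_to_grey(self):
        a = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        mods = detect_modules(a, NetworkParams(min_module_size=50))
        assert [m.label for m in mods] == ["grey"]


class TestEigengene:
    def test_identical_profiles_recover_standardized_profile(self, samples12):
        profile = np.arange(12, dtype=float)
        vals = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)],
                            columns=samples12.index)
        e = eigengene(list(vals.index), vals)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(e.values, z, atol=1e-10)
        assert e.std(ddof=1) == pytest.approx(1.0)

    def test_orientation_non_negative_mean_member_correlation(self, rng,
                                                              samples12):
        f = rng.standard_normal(12)
        vals = pd.DataFrame([f + 0.1 * rng.standard_normal(12)
                             for _ in range(20)],
                            index=[f"g{i}" for i in range(20)],
                            columns=samples12.index)
        e = eigengene(list(vals.index), vals)
        corrs = [np.corrcoef(vals.loc[g], e)[0, 1] for g in vals.index]
        assert np.mean(corrs) >= 0


class TestMergeAndTrait:
    def chain_matrix(self, rng, samples):
        """Three modules whose eigengenes correlate A~B, B~C strongly."""
        f = rng.standard_normal(12)
        g = f + 0.35 * rng.standard_normal(12)
        h = g + 0.35 * rng.standard_normal(12)
        rows = {}
        for i, base in enumerate((f, g, h)):
            for j in range(10):
                rows[f"m{i}_{j}"] = base + 0.05 * rng.standard_normal(12)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=samples.index)

    def test_similar_eigengenes_merge_chain_into_one(self, rng, samples12):
        vals = self.chain_matrix(rng, samples12)
        mods = [CoexpressionModule("a", [f"m0_{j}" for j in range(10)]),
                CoexpressionModule("b", [f"m1_{j}" for j in range(10)]),
                CoexpressionModule("c", [f"m2_{j}" for j in range(10)])]
        merged = merge_modules(mods, vals, merge_similarity=0.8)
        real = [m for m in merged if m.label != "grey"]
        assert len(real) == 1
        assert real[0].size == 30

    def test_dissimilar_modules_stay_separate(self, rng, samples12):
        f = rng.standard_normal(12)
        g = rng.standard_normal(12)
        g = g - f * (f @ g) / (f @ f)  # orthogonalize
        rows = {f"a{j}": f + 0.05 * rng.standard_normal(12) for j in range(10)}
        rows.update({f"b{j}": g + 0.05 * rng.standard_normal(12)
                     for j in range(10)})
        vals = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=samples12.index)
        mods = [CoexpressionModule("a", [f"a{j}" for j in range(10)]),
                CoexpressionModule("b", [f"b{j}" for j in range(10)])]
        merged = merge_modules(mods, vals, merge_similarity=0.8)
        assert len([m for m in merged if m.label != "grey"]) == 2

    def test_trait_identical_to_eigengene_gives_unit_correlation(
            self, rng, samples12):
        f = rng.standard_normal(12)
        vals = pd.DataFrame([f + 0.01 * rng.standard_normal(12)
                             for _ in range(10)],
                            index=[f"g{i}" for i in range(10)],
                            columns=samples12.index)
        m = CoexpressionModule("blue", list(vals.index))
        m.eigengene = eigengene(m.members, vals)
        table = module_trait([m], m.eigengene)
        assert table.iloc[0]["r"] == pytest.approx(1.0)
        negated = module_trait([m], -m.eigengene)
        assert negated.iloc[0]["r"] == pytest.approx(-1.0)


class TestHubs:
    def module_with_kme(self, kme: dict):
        m = CoexpressionModule("blue", sorted(kme))
        m.kme = pd.Series(kme)
        return m

    def test_ceil_rule_sizes(self):
        m1000 = self.module_with_kme({f"g{i:04d}": 1 - i * 1e-4
                                      for i in range(1000)})
        assert len(select_hubs(m1000)) == 1
        m50 = self.module_with_kme({f"g{i:02d}": 1 - i * 1e-3
                                    for i in range(50)})
        assert len(select_hubs(m50)) == 1
        m2000 = self.module_with_kme({f"g{i:04d}": 1 - i * 1e-4
                                      for i in range(2000)})
        assert len(select_hubs(m2000)) == 2

    def test_highest_kme_wins_ties_lexicographic(self):
        m = self.module_with_kme({"b": 0.9, "a": 0.9, "c": 0.5})
        assert select_hubs(m) == ["a"]


def test_dendrogram_newick_has_all_leaves(rng, samples12):
    vals = pd.DataFrame(rng.standard_normal((6, 12)),
                        index=[f"g{i}" for i in range(6)],
                        columns=samples12.index)
    t = tom(adjacency(vals, 2))
    nwk = dendrogram_newick(t)
    assert nwk.endswith(";")
    for g in vals.index:
        assert g in nwk
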