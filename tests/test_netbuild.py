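"""Regulatory-network assembly, neighbors, and exports."""

import numpy as np
import pandas as pd
import pytest

from mirnet.coexpr import CoexpressionModule
from mirnet.netbuild import (RegulatoryNetwork, assemble,
                             expression_correlation, map_to_modules,
                             mirna_tf_pairs, neighbors)
from mirnet.quant import ExpressionMatrix


class TestMapToModules:
    def test_de_gene_counted_under_its_module_and_unassigned_listed(self):
        de = pd.DataFrame({"id": ["g1", "g2", "g3"],
                           "is_de": [True, True, False]})
        modules = [CoexpressionModule("blue", ["g1", "g9"])]
        table, unassigned = map_to_modules(de, modules)
        assert table.to_dict("records") == [{"module": "blue", "id": "g1"}]
        assert unassigned == ["g2"]


class TestNeighbors:
    def test_k_zero_returns_empty(self, count_matrix):
        assert neighbors(count_matrix.entities[0], count_matrix, 0) == []

    def test_duplicated_profile_ranks_first_with_unit_correlation(
            self, samples12, rng):
        f = rng.standard_normal(12)
        vals = pd.DataFrame(
            {"focus": f, "copy": 2 * f + 1,
             **{f"g{i}": rng.standard_normal(12) for i in range(8)}},
        ).T
        vals.columns = samples12.index
        out = neighbors("focus", vals, 3)
        assert out[0][0] == "copy"
        assert abs(out[0][1]) == pytest.approx(1.0)

    def test_rank_agreement_with_bruteforce_sort(self, samples12, rng):
        vals = pd.DataFrame(rng.standard_normal((100, 12)),
                            index=[f"g{i:03d}" for i in range(100)],
                            columns=samples12.index)
        out = neighbors("g000", vals, 10)
        f = vals.loc["g000"]
        expected = sorted(
            ((g, float(np.corrcoef(f, vals.loc[g])[0, 1]))
             for g in vals.index if g != "g000"),
            key=lambda gr: (-abs(gr[1]), gr[0]),
        )[:10]
        assert [g for g, _ in out] == [g for g, _ in expected]


class TestMirnaTfPairs:
    CALLS = pd.DataFrame([
        {"mirna_id": "mir1", "transcript_id": "SPL9", "cleavage_pos": 100,
         "score": 0.5, "site_count": 50, "max_count": 50,
         "median_nonzero": 3.0, "category": 0, "kept": True},
        {"mirna_id": "mir1", "transcript_id": "nontf", "cleavage_pos": 80,
         "score": 1.0, "site_count": 40, "max_count": 40,
         "median_nonzero": 3.0, "category": 0, "kept": True},
        {"mirna_id": "mir2", "transcript_id": "SPL9", "cleavage_pos": 100,
         "score": 1.0, "site_count": 1, "max_count": 50,
         "median_nonzero": 3.0, "category": 4, "kept": False},
    ])
    TF = {"SPL9": "SBP"}

    def test_kept_tf_call_from_demir_becomes_edge(self):
        edges = mirna_tf_pairs(self.CALLS, self.TF, {"mir1", "mir2"})
        assert len(edges) == 1
        assert edges.iloc[0]["mirna_id"] == "mir1"
        assert edges.iloc[0]["tf_family"] == "SBP"

    def test_non_demir_and_unkept_calls_excluded(self):
        assert mirna_tf_pairs(self.CALLS, self.TF, {"mir2"}).empty


class TestExpressionCorrelation:
    def test_affine_anti_regulation_gives_minus_one(self, samples12):
        m_vals = pd.DataFrame(
            [[10, 10, 10, 20, 20, 20, 40, 40, 40, 80, 80, 80]],
            index=["mir1"], columns=samples12.index, dtype=float)
        t_vals = pd.DataFrame(
            [[90, 90, 90, 80, 80, 80, 60, 60, 60, 20, 20, 20]],
            index=["g1"], columns=samples12.index, dtype=float)
        m = ExpressionMatrix(m_vals, samples12, "TPM")
        t = ExpressionMatrix(t_vals, samples12, "FPKM")
        res = expression_correlation(m, t, [("mir1", "g1")])
        assert res.iloc[0]["r"] == pytest.approx(-1.0)

    def test_constant_profile_reported_missing(self, samples12):
        m = ExpressionMatrix(
            pd.DataFrame([[5.0] * 12], index=["mir1"],
                         columns=samples12.index), samples12, "TPM")
        t = ExpressionMatrix(
            pd.DataFrame([np.arange(12.0)], index=["g1"],
                         columns=samples12.index), samples12, "FPKM")
        res = expression_correlation(m, t, [("mir1", "g1")])
        assert np.isnan(res.iloc[0]["r"])


class TestAssemble:
    def fixture(self, rng, samples12):
        f = rng.standard_normal(12)
        rows = {"TF1": f + 0.01 * rng.standard_normal(12)}
        for i in range(6):
            rows[f"g{i}"] = f + (0.05 + 0.05 * i) * rng.standard_normal(12)
        vals = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=samples12.index)
        module = CoexpressionModule("blue", sorted(rows))
        edges = pd.DataFrame([{"mirna_id": "mir1", "target_id": "TF1",
                               "tf_family": "SBP", "score": 0.5,
                               "category": 0}])
        return [module], edges, vals

    def test_single_pair_with_two_neighbors(self, rng, samples12):
        modules, edges, vals = self.fixture(rng, samples12)
        net = assemble(modules, edges, vals, k_neighbors=2)
        assert net.n_nodes == 4  # miRNA + TF + 2 neighbors
        assert net.n_edges == 3  # 1 targeting + 2 coexpression
        targeting = net.edges[net.edges["type"] == "targeting"]
        assert list(zip(targeting["source"], targeting["target"])) == [
            ("mir1", "TF1")]

    def test_no_targeting_edges_gives_empty_network(self, rng, samples12):
        modules, _, vals = self.fixture(rng, samples12)
        empty_edges = pd.DataFrame(
            columns=["mirna_id", "target_id", "tf_family", "score",
                     "category"])
        net = assemble(modules, empty_edges, vals, k_neighbors=2)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_empty_module_list_warns_and_returns_empty(self, rng, samples12):
        _, edges, vals = self.fixture(rng, samples12)
        with pytest.warns(UserWarning):
            net = assemble([], edges, vals, k_neighbors=2)
        assert net.n_nodes == 0

    def test_referential_integrity_enforced(self):
        nodes = pd.DataFrame([{"id": "a", "role": "miRNA", "module": "",
                               "de_status": ""}])
        edges = pd.DataFrame([{"source": "a", "target": "ghost",
                               "type": "targeting", "weight": 1.0}])
        with pytest.raises(ValueError, match="ghost"):
            RegulatoryNetwork(nodes, edges)

    def test_targeting_edges_must_come_from_mirnas(self):
        nodes = pd.DataFrame([
            {"id": "a", "role": "gene", "module": "", "de_status": ""},
            {"id": "b", "role": "TF", "module": "", "de_status": ""}])
        edges = pd.DataFrame([{"source": "a", "target": "b",
                               "type": "targeting", "weight": 1.0}])
        with pytest.raises(ValueError, match="miRNA"):
            RegulatoryNetwork(nodes, edges)

    def test_exports_are_cytoscape_loadable(self, rng, samples12, tmp_path):
        modules, edges, vals = self.fixture(rng, samples12)
        net = assemble(modules, edges, vals, k_neighbors=2)
        net.write_sif(tmp_path / "n.sif")
        net.write_graphml(tmp_path / "n.graphml")
        sif_lines = (tmp_path / "n.sif").read_text().strip().split("\n")
        assert len(sif_lines) == net.n_edges
        assert all(len(l.split("\t")) == 3 for l in sif_lines)
        import networkx as nx
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.number_of_nodes() == net.n_nodes
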