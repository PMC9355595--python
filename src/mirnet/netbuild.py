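"""Assembly of the integrated miRNA -> transcription-factor regulatory network.

Nodes are typed (miRNA, TF, gene) and edges are either ``targeting`` (a
degradome-validated miRNA -> target relation, directed) or ``coexpression``
(an undirected |Pearson r| relation, stored with canonical endpoint order).
The network combines differentially expressed miRNAs, their validated
transcription-factor targets inside trait-associated co-expression modules,
and the strongest co-expression neighbors of those TFs, and is exportable in
Cytoscape-loadable formats (SIF, GraphML, node/edge attribute tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .coexpr import CoexpressionModule, GREY
from .quant import ExpressionMatrix

NODE_COLUMNS = ["id", "role", "module", "de_status"]
EDGE_COLUMNS = ["source", "target", "type", "weight"]


@dataclass
class RegulatoryNetwork:
    """Typed node and edge tables with referential integrity checks."""

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self):
        if self.nodes.empty:
            self.nodes = pd.DataFrame(columns=NODE_COLUMNS)
        if self.edges.empty:
            self.edges = pd.DataFrame(columns=EDGE_COLUMNS)
        self.validate()

    def validate(self) -> None:
        ids = set(self.nodes["id"])
        for col in ("source", "target"):
            stray = set(self.edges[col]) - ids
            if stray:
                raise ValueError(f"edge endpoint(s) missing from nodes: {sorted(stray)}")
        roles = dict(zip(self.nodes["id"], self.nodes["role"]))
        targeting = self.edges[self.edges["type"] == "targeting"]
        bad = [s for s in targeting["source"] if roles.get(s) != "miRNA"]
        if bad:
            raise ValueError(f"targeting edges must originate from miRNAs: {bad}")
        coex = self.edges[self.edges["type"] == "coexpression"]
        unordered = coex[coex["source"] > coex["target"]]
        if len(unordered):
            raise ValueError("coexpression edges must be stored in canonical order")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for r in self.nodes.itertuples(index=False):
            g.add_node(r.id, role=r.role, module=r.module, de_status=r.de_status)
        for e in self.edges.itertuples(index=False):
            g.add_edge(e.source, e.target, type=e.type, weight=float(e.weight))
        return g

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.edges.itertuples(index=False):
                fh.write(f"{e.source}\t{e.type}\t{e.target}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_tables(self, node_path, edge_path) -> None:
        self.nodes.to_csv(node_path, sep="\t", index=False)
        self.edges.to_csv(edge_path, sep="\t", index=False)


def map_to_modules(
    de_results: pd.DataFrame,
    modules: list[CoexpressionModule],
) -> tuple[pd.DataFrame, list[str]]:
    """Partition DE entities over modules.

    Returns a (module, id) table of DE members per module and the list of DE
    entities carried by no module (e.g. filtered out before the network step).
    """
    de_ids = list(de_results.loc[de_results["is_de"], "id"])
    assignment = {g: m.label for m in modules for g in m.members}
    rows = [
        {"module": assignment[g], "id": g} for g in de_ids if g in assignment
    ]
    unassigned = sorted(g for g in de_ids if g not in assignment)
    return pd.DataFrame(rows, columns=["module", "id"]), unassigned


def neighbors(
    focus: str,
    matrix: ExpressionMatrix | pd.DataFrame,
    k: int,
    restrict_to: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Top-k most connected entities: highest |Pearson r| with the focus.

    ``restrict_to`` limits candidates (e.g. to the focus module); the focus
    itself is excluded; ties break lexicographically by id.
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if k == 0:
        return []
    if focus not in vals.index:
        raise KeyError(f"focus entity {focus!r} not in matrix")
    pool = [g for g in (restrict_to if restrict_to is not None else vals.index)
            if g != focus and g in vals.index]
    f = vals.loc[focus].values.astype(float)
    scored = []
    for g in pool:
        r = np.corrcoef(f, vals.loc[g].values.astype(float))[0, 1]
        if np.isnan(r):
            continue
        scored.append((g, float(r)))
    scored.sort(key=lambda gr: (-abs(gr[1]), gr[0]))
    return scored[:k]


def mirna_tf_pairs(
    calls: pd.DataFrame,
    tf_annotation: dict[str, str],
    demirs: set[str],
) -> pd.DataFrame:
    """Validated miRNA -> TF targeting edges.

    Keeps degradome calls with ``kept = True`` whose target carries a TF
    family annotation and whose miRNA is differentially expressed; one edge
    per (miRNA, target) pair.
    """
    kept = calls[calls["kept"]]
    rows = []
    seen = set()
    for c in kept.itertuples(index=False):
        key = (c.mirna_id, c.transcript_id)
        if key in seen:
            continue
        if c.transcript_id in tf_annotation and c.mirna_id in demirs:
            seen.add(key)
            rows.append(
                {"mirna_id": c.mirna_id, "target_id": c.transcript_id,
                 "tf_family": tf_annotation[c.transcript_id],
                 "score": c.score, "category": c.category}
            )
    return pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "tf_family", "score", "category"]
    )


def expression_correlation(
    mirna_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Pearson r of stage-mean miRNA vs stage-mean target expression.

    Correlations run across the developmental stages (means over replicates);
    a constant profile makes r undefined and is reported as missing (NaN).
    """
    m_means = mirna_expr.stage_means()
    t_means = target_expr.stage_means()
    rows = []
    for mid, tid in pairs:
        x = m_means.loc[mid].values.astype(float)
        y = t_means.loc[tid].values.astype(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"mirna_id": mid, "target_id": tid, "r": r})
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "r"])


def assemble(
    trait_modules: list[CoexpressionModule],
    targeting_edges: pd.DataFrame,
    matrix: ExpressionMatrix | pd.DataFrame,
    k_neighbors: int = 10,
    de_status: dict[str, str] | None = None,
) -> RegulatoryNetwork:
    """Assemble the regulatory network around validated miRNA -> TF pairs.

    Nodes: DE miRNAs with TF targets inside the trait-associated modules, the
    TFs themselves, and the ``k_neighbors`` strongest co-expression neighbors
    of each TF within its module.  Edges: the targeting pairs plus TF-neighbor
    co-expression edges weighted by |r|.
    """
    de_status = de_status or {}
    module_of = {g: m.label for m in trait_modules for g in m.members}
    import warnings

    if not trait_modules:
        warnings.warn("no trait-associated modules: assembling an empty network")
        return RegulatoryNetwork(pd.DataFrame(columns=NODE_COLUMNS),
                                 pd.DataFrame(columns=EDGE_COLUMNS))

    nodes: dict[str, dict] = {}
    edges: list[dict] = []

    def add_node(nid: str, role: str):
        nodes.setdefault(
            nid,
            {"id": nid, "role": role, "module": module_of.get(nid, ""),
             "de_status": de_status.get(nid, "")},
        )

    mask = targeting_edges["target_id"].map(module_of.__contains__).astype(bool)
    in_modules = targeting_edges.loc[mask]
    for e in in_modules.itertuples(index=False):
        add_node(e.mirna_id, "miRNA")
        add_node(e.target_id, "TF")
        edges.append({"source": e.mirna_id, "target": e.target_id,
                      "type": "targeting", "weight": float(e.score)})

    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    for tf in sorted(set(in_modules["target_id"])):
        if tf not in vals.index:
            continue
        members = next(
            (m.members for m in trait_modules if tf in m.members), None)
        for g, r in neighbors(tf, vals, k_neighbors, restrict_to=members):
            add_node(g, nodes.get(g, {}).get("role", "gene"))
            a, b = sorted((tf, g))
            edges.append({"source": a, "target": b,
                          "type": "coexpression", "weight": abs(r)})

    node_df = pd.DataFrame(list(nodes.values()), columns=NODE_COLUMNS)
    edge_df = pd.DataFrame(edges, columns=EDGE_COLUMNS).drop_duplicates(
        subset=["source", "target", "type"]
    ).reset_index(drop=True)
    return RegulatoryNetwork(node_df, edge_df)
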