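"""Weighted co-expression network analysis: adjacency, TOM, modules, traits.

The pipeline mirrors the classic weighted-network workflow: entities passing
an expression filter are correlated (Pearson), the correlation is soft-
thresholded into an adjacency ``a_ij = |r_ij|^beta`` (unsigned network;
``beta`` = 9 for genes and 8 for miRNAs by default), the adjacency is
smoothed into the topological overlap measure

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

and 1 - TOM is clustered by average-linkage hierarchical clustering.  The
tree is cut at a static height (default 0.99); branches smaller than the
minimum module size (default 50) are pooled into the unassigned "grey"
module.  Modules are named from a fixed color palette by decreasing size,
merged when their eigengenes correlate at or above the merge threshold
(default 0.8), and related to a sample trait through the Pearson correlation
of the module eigengene with the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quant import ExpressionMatrix

GREY = "grey"

#: ordered palette for module naming (largest module first)
COLOR_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class NetworkParams:
    """Tunable parameters of the co-expression pipeline."""

    soft_power: int = 9
    min_module_size: int = 50
    merge_similarity: float = 0.8
    cut_height: float = 0.99
    min_value: float = 2.0
    min_fraction: float = 0.7
    min_sd: float = 0.25
    min_kme: float = 0.7
    log2: bool = True
    signed: bool = False

    def __post_init__(self):
        if self.soft_power < 1:
            raise ValueError("soft_power must be a positive integer")
        if not 0 < self.merge_similarity < 1:
            raise ValueError("merge_similarity must be in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


MIRNA_PARAMS = NetworkParams(soft_power=8)


@dataclass
class CoexpressionModule:
    """A co-expression module with its eigengene and trait association."""

    label: str
    members: list[str]
    eigengene: pd.Series | None = None
    kme: pd.Series | None = None
    trait_r: float | None = None
    trait_p: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def filter_expressed(matrix: ExpressionMatrix, params: NetworkParams) -> ExpressionMatrix:
    """Keep entities expressed >= min_value in >= min_fraction of samples
    with sample standard deviation > min_sd."""
    if matrix.units not in ("FPKM", "TPM"):
        raise ValueError("expression filter expects FPKM or TPM units")
    vals = matrix.values
    frac = (vals >= params.min_value).mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    keep = (frac >= params.min_fraction) & (sd > params.min_sd)
    return ExpressionMatrix(vals.loc[keep], matrix.samples, matrix.units)


def adjacency(matrix: ExpressionMatrix | pd.DataFrame, beta: int,
              signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency from Pearson correlations of row profiles.

    Unsigned (default): ``a = |r|^beta``; signed: ``a = ((1+r)/2)^beta``.
    The diagonal is 1.
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    r = np.corrcoef(vals.values)
    r = np.nan_to_num(r, nan=0.0)
    a = ((1 + r) / 2) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=vals.index, columns=vals.index)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap measure of a symmetric adjacency in [0, 1]."""
    a = adj.values.astype(float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency matrix must be symmetric")
    n = len(a)
    a = a.copy()
    np.fill_diagonal(a, 0.0)  # self-edges excluded from k and l
    k = a.sum(axis=1)
    l = a @ a  # (A^2)_ij = sum_u a_iu a_uj; diagonal of a is 0 so u != i, j
    t = (l + a) / (np.minimum.outer(k, k) + 1 - a)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def linkage_tree(tom_df: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of the 1 - TOM dissimilarity."""
    dissim = 1.0 - tom_df.values
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    return hierarchy.linkage(condensed, method="average")


def detect_modules(tom_df: pd.DataFrame, params: NetworkParams) -> list[CoexpressionModule]:
    """Cut the dendrogram at a static height into modules.

    Branches below ``min_module_size`` members are pooled into "grey".
    Modules are labelled from the color palette by decreasing size (ties by
    smallest member id).  The grey pool, possibly empty, is always last.
    """
    ids = list(tom_df.index)
    if len(ids) < params.min_module_size:
        return [CoexpressionModule(GREY, ids)]
    z = linkage_tree(tom_df)
    flat = hierarchy.fcluster(z, t=params.cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for gid, cl in zip(ids, flat):
        clusters.setdefault(int(cl), []).append(gid)
    real = [m for m in clusters.values() if len(m) >= params.min_module_size]
    grey = sorted(
        g for m in clusters.values() if len(m) < params.min_module_size for g in m
    )
    real.sort(key=lambda m: (-len(m), sorted(m)[0]))
    modules = [
        CoexpressionModule(COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module{i + 1}",
                           sorted(m))
        for i, m in enumerate(real)
    ]
    modules.append(CoexpressionModule(GREY, grey))
    return modules


def eigengene(members: list[str], matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """First principal component of the standardized member profiles.

    Scaled to unit variance over samples and oriented so the mean member
    correlation with the eigengene is non-negative.
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    x = vals.loc[members].values.astype(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    # first right singular vector = leading PC over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    e = e / e.std(ddof=1)
    corr = np.array([np.corrcoef(z[i], e)[0, 1] for i in range(len(members))])
    if np.nanmean(corr) < 0:
        e = -e
    return pd.Series(e, index=vals.columns)


def module_kme(module: CoexpressionModule, matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Module membership: Pearson correlation of each member with the eigengene."""
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    e = module.eigengene
    if e is None:
        raise ValueError("module has no eigengene; compute it first")
    kme = {
        g: float(np.corrcoef(vals.loc[g].values.astype(float), e.values)[0, 1])
        for g in module.members
    }
    return pd.Series(kme)


def fill_eigengenes(modules: list[CoexpressionModule],
                    matrix: ExpressionMatrix | pd.DataFrame) -> list[CoexpressionModule]:
    """Compute eigengene and kME for every non-empty, non-grey module."""
    for m in modules:
        if m.label != GREY and m.members:
            m.eigengene = eigengene(m.members, matrix)
            m.kme = module_kme(m, matrix)
    return modules


def screen_membership(modules: list[CoexpressionModule],
                      matrix: ExpressionMatrix | pd.DataFrame,
                      min_kme: float,
                      min_module_size: int) -> list[CoexpressionModule]:
    """Dissolve incoherent modules by module membership.

    A static-height tree cut can agglomerate unstructured entities into a
    branch large enough to pass the size rule; genuine modules are
    distinguished by high member kME.  Members below ``min_kme`` move to the
    grey pool, and modules dropping under ``min_module_size`` dissolve
    entirely.  ``min_kme = 0`` disables the screen.
    """
    if min_kme <= 0:
        return modules
    kept: list[list[str]] = []
    grey: list[str] = []
    for m in modules:
        if m.label == GREY:
            grey.extend(m.members)
            continue
        if m.kme is None:
            m.eigengene = eigengene(m.members, matrix)
            m.kme = module_kme(m, matrix)
        good = [g for g in m.members if m.kme[g] >= min_kme]
        if len(good) >= min_module_size:
            kept.append(sorted(good))
            grey.extend(g for g in m.members if g not in set(good))
        else:
            grey.extend(m.members)
    kept.sort(key=lambda mm: (-len(mm), mm[0]))
    out = [
        CoexpressionModule(
            COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module{i + 1}",
            mm)
        for i, mm in enumerate(kept)
    ]
    out.append(CoexpressionModule(GREY, sorted(grey)))
    fill_eigengenes(out, matrix)
    return out


def reassign_by_kme(modules: list[CoexpressionModule],
                    matrix: ExpressionMatrix | pd.DataFrame,
                    min_kme: float,
                    min_module_size: int) -> list[CoexpressionModule]:
    """Reassign every entity to its best-fitting module eigengene.

    The screened module cores give nearly noise-free eigengenes; each entity
    (module member or grey) then joins the module whose eigengene it
    correlates with most, provided that kME reaches ``min_kme``, and falls to
    grey otherwise.  This recovers borderline members the tree cut or the
    membership screen dropped, the same way the partitioning-around-medoids
    stage of dynamic tree cutting does.
    """
    cores = [m for m in modules if m.label != GREY and m.members]
    if not cores or min_kme <= 0:
        return modules
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    for m in cores:
        if m.eigengene is None:
            m.eigengene = eigengene(m.members, matrix)
    eig = np.stack([m.eigengene.values for m in cores])
    x = vals.values.astype(float)
    xz = (x - x.mean(1, keepdims=True))
    xn = xz / np.where(np.linalg.norm(xz, axis=1, keepdims=True) == 0, 1,
                       np.linalg.norm(xz, axis=1, keepdims=True))
    ez = eig - eig.mean(1, keepdims=True)
    en = ez / np.linalg.norm(ez, axis=1, keepdims=True)
    kme_all = xn @ en.T  # entities x modules
    best = kme_all.argmax(1)
    best_kme = kme_all[np.arange(len(x)), best]
    assigned: dict[int, list[str]] = {}
    grey: list[str] = []
    for gi, g in enumerate(vals.index):
        if best_kme[gi] >= min_kme:
            assigned.setdefault(int(best[gi]), []).append(g)
        else:
            grey.append(g)
    member_lists = [sorted(mm) for mm in assigned.values()
                    if len(mm) >= min_module_size]
    for mm in assigned.values():
        if len(mm) < min_module_size:
            grey.extend(mm)
    member_lists.sort(key=lambda mm: (-len(mm), mm[0]))
    out = [
        CoexpressionModule(
            COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module{i + 1}",
            mm)
        for i, mm in enumerate(member_lists)
    ]
    out.append(CoexpressionModule(GREY, sorted(grey)))
    fill_eigengenes(out, matrix)
    return out


def merge_modules(modules: list[CoexpressionModule],
                  matrix: ExpressionMatrix | pd.DataFrame,
                  merge_similarity: float = 0.8) -> list[CoexpressionModule]:
    """Iteratively merge module pairs with eigengene correlation >= threshold.

    The most similar pair merges first; eigengenes are recomputed after each
    merge, so chained similarities collapse into one module.  Labels are
    reassigned from the palette by decreasing size afterwards.
    """
    work = [list(m.members) for m in modules if m.label != GREY and m.members]
    grey = next((m for m in modules if m.label == GREY), None)
    while len(work) > 1:
        eigs = [eigengene(m, matrix).values for m in work]
        best, best_r = None, -np.inf
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                r = float(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if r > best_r:
                    best, best_r = (i, j), r
        if best_r < merge_similarity:
            break
        i, j = best
        work[i] = sorted(work[i] + work[j])
        del work[j]
    work.sort(key=lambda m: (-len(m), sorted(m)[0]))
    out = [
        CoexpressionModule(
            COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module{i + 1}",
            sorted(m))
        for i, m in enumerate(work)
    ]
    if grey is not None:
        out.append(grey)
    fill_eigengenes(out, matrix)
    return out


def module_trait(modules: list[CoexpressionModule], trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a per-sample trait."""
    rows = []
    for m in modules:
        if m.eigengene is None:
            continue
        e = m.eigengene.loc[trait.index]
        r, p = stats.pearsonr(e.values, trait.values)
        m.trait_r, m.trait_p = float(r), float(p)
        rows.append({"module": m.label, "r": m.trait_r, "p": m.trait_p,
                     "size": m.size})
    return pd.DataFrame(rows, columns=["module", "r", "p", "size"])


def select_hubs(module: CoexpressionModule, top_fraction: float = 0.001) -> list[str]:
    """Hub members: the ceil(top_fraction * size) highest-kME members.

    Always returns at least one member; ties break lexicographically by id.
    """
    if module.kme is None:
        raise ValueError("module has no kME; compute eigengene/kME first")
    n = max(1, ceil(top_fraction * module.size))
    ranked = sorted(module.kme.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:n]]


def dendrogram_newick(tom_df: pd.DataFrame) -> str:
    """Average-linkage tree of 1 - TOM as a Newick string (for inspection)."""
    z = linkage_tree(tom_df)
    tree = hierarchy.to_tree(z)
    ids = list(tom_df.index)

    def rec(node):
        if node.is_leaf():
            return ids[node.id]
        return f"({rec(node.left)}:{node.dist / 2:.6g},{rec(node.right)}:{node.dist / 2:.6g})"

    return rec(tree) + ";"


def coexpression_pipeline(
    matrix: ExpressionMatrix,
    params: NetworkParams,
    trait: pd.Series | None = None,
) -> tuple[list[CoexpressionModule], pd.DataFrame]:
    """Filter, build TOM, detect and merge modules, and associate a trait.

    Returns the merged module list (eigengenes and kME filled) and the
    module-trait table (empty if no trait is given).
    """
    filtered = filter_expressed(matrix, params)
    if params.log2:
        # variance-stabilize before correlating; the expression filter above
        # still sees the original FPKM/TPM scale its thresholds refer to
        filtered = ExpressionMatrix(np.log2(filtered.values + 1.0),
                                    filtered.samples, filtered.units)
    adj = adjacency(filtered, params.soft_power, signed=params.signed)
    t = tom(adj)
    modules = detect_modules(t, params)
    fill_eigengenes(modules, filtered)
    modules = screen_membership(modules, filtered, params.min_kme,
                                params.min_module_size)
    modules = reassign_by_kme(modules, filtered, params.min_kme,
                              params.min_module_size)
    modules = merge_modules(modules, filtered, params.merge_similarity)
    trait_table = pd.DataFrame(columns=["module", "r", "p", "size"])
    if trait is not None:
        trait_table = module_trait(modules, trait)
    return modules, trait_table
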