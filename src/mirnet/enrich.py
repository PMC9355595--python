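"""Hypergeometric term enrichment with Benjamini-Hochberg FDR control.

For a term annotating M of N background genes, with n candidate genes of
which m are annotated, the enrichment p-value is the upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N - M, n - i) / C(N, n),

i.e. the probability of drawing at least m annotated genes in n draws
without replacement.  Terms with no candidate overlap (m = 0) are excluded
from testing so they do not dilute the FDR correction; annotations are taken
as flat sets (no ontology-graph propagation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TermAnnotation:
    """One annotation term and its annotated entity set."""

    term_id: str
    name: str
    namespace: str  # BP | MF | CC | pathway
    entities: frozenset[str]


def hypergeom_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability of >= m annotated candidates.

    ``N`` background genes, ``n`` candidates, ``M`` annotated in background,
    ``m`` annotated candidates.
    """
    if min(N, n, M, m) < 0:
        raise ValueError("counts must be non-negative")
    if m > min(n, M) or N < max(n, M):
        raise ValueError(
            f"invalid counts: need m <= min(n, M) and N >= max(n, M); "
            f"got N={N}, n={n}, M={M}, m={m}"
        )
    # survival function at m-1: P(X >= m)
    return float(stats.hypergeom.sf(m - 1, N, M, n))


RESULT_COLUMNS = ["term_id", "name", "namespace", "N", "n", "M", "m", "p",
                  "fdr", "significant"]


def enrich(
    candidates: set[str],
    annotations: list[TermAnnotation],
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each term for over-representation among the candidate genes.

    The background defaults to the union of all annotated entities.  Terms
    overlapping no candidate are skipped; p-values of the tested terms are
    BH-adjusted and a term is significant when its FDR <= ``alpha``.
    Results are sorted by p-value.
    """
    if background is None:
        background = set().union(*(a.entities for a in annotations)) if annotations else set()
    background = set(background)
    stray = set(candidates) - background
    if stray:
        raise ValueError(f"candidates outside background: {sorted(stray)}")

    N, n = len(background), len(candidates)
    rows = []
    for a in annotations:
        annotated = a.entities & background
        M = len(annotated)
        m = len(candidates & annotated)
        if m == 0:
            continue
        rows.append(
            {"term_id": a.term_id, "name": a.name, "namespace": a.namespace,
             "N": N, "n": n, "M": M, "m": m, "p": hypergeom_p(N, n, M, m)}
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
    out["significant"] = out["fdr"] <= alpha
    return out.sort_values(["p", "term_id"]).reset_index(drop=True)[RESULT_COLUMNS]


def read_annotations(path) -> list[TermAnnotation]:
    """Read a TSV of (entity, term, name, namespace) into term annotations."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (term, name, ns), grp in df.groupby(["term", "name", "namespace"], sort=True):
        out.append(TermAnnotation(term, name, ns, frozenset(grp["entity"])))
    return out


def write_annotations(annotations: list[TermAnnotation], path) -> None:
    rows = [
        {"entity": e, "term": a.term_id, "name": a.name, "namespace": a.namespace}
        for a in annotations
        for e in sorted(a.entities)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
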