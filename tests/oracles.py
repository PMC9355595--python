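"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the rule statements directly, in plain
Python, with no imports from the package's computational code paths, so a
bug in the fast implementations cannot hide in its own oracle.
"""

from __future__ import annotations

from itertools import combinations

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
WOBBLE = {("G", "U"), ("U", "G")}
ENERGY = {"A": -2.0, "U": -2.0, "G": -3.0, "C": -3.0}


def pair_class(mirna_base: str, transcript_base: str) -> str:
    if COMPLEMENT[mirna_base] == transcript_base:
        return "WC"
    if (mirna_base, transcript_base) in WOBBLE:
        return "GU"
    return "MM"


def bf_placements(mirna: str, window: str):
    """All gap placements of one window, as (states, positions) pairs.

    States run along the duplex in miRNA 5'->3' order, the window being read
    3'->5'.  A longer window leaves one transcript base bulged (GAP state at
    a half-integer miRNA position); a shorter window leaves one miRNA
    position unpaired (GAP at that integer position).  Placements are listed
    leftmost-gap-first in duplex order.
    """
    L, W = len(mirna), len(window)
    rev = window[::-1]  # read 3'->5'
    if W == L:
        states = [pair_class(mirna[i], rev[i]) for i in range(L)]
        return [(states, [float(i + 1) for i in range(L)])]
    if W == L + 1:
        out = []
        for k in range(L + 1):  # GAP at duplex state index k
            states, positions = [], []
            mi = 0
            for s in range(L + 1):
                if s == k:
                    states.append("GAP")
                    positions.append(mi + 0.5)
                else:
                    states.append(pair_class(mirna[mi], rev[s]))
                    positions.append(float(mi + 1))
                    mi += 1
            out.append((states, positions))
        return out
    if W == L - 1:
        out = []
        for g in range(L):  # miRNA position g+1 unpaired
            states, positions = [], []
            wi = 0
            for i in range(L):
                if i == g:
                    states.append("GAP")
                else:
                    states.append(pair_class(mirna[i], rev[wi]))
                    wi += 1
                positions.append(float(i + 1))
            out.append((states, positions))
        return out
    raise ValueError("window length outside miRNA length +/- 1")


def bf_best_placement(mirna: str, window: str):
    """Max Watson-Crick pairs; ties go to the leftmost gap in duplex order."""
    placements = bf_placements(mirna, window)
    best = placements[0]
    for cand in placements[1:]:
        if cand[0].count("WC") > best[0].count("WC"):
            best = cand
    return best


def bf_score(states) -> float:
    return (states.count("MM") + 0.5 * states.count("GU")
            + states.count("GAP"))


def bf_mfe_ratio(mirna: str, states, positions) -> float:
    e_perfect = sum(ENERGY[b] for b in mirna)
    e = 0.0
    for s, p in zip(states, positions):
        if s == "WC":
            e += ENERGY[mirna[int(p) - 1]]
        elif s == "GU":
            e += -1.0
    return 100.0 * e / e_perfect


def bf_verdict(mirna: str, states, positions) -> dict:
    """Literal application of the six screening criteria."""
    mmlike = [s in ("MM", "GAP") for s in states]
    in_region = [2 <= p <= 12 for p in positions]
    adj = [mmlike[i] and mmlike[i + 1] for i in range(len(states) - 1)]
    v = {
        "c1": bf_mfe_ratio(mirna, states, positions) >= 74.0,
        "c2": bf_score(states) <= 4.0,
        "c3": sum(adj) <= 2,
        "c4": not any(adj[i] and in_region[i] and in_region[i + 1]
                      for i in range(len(adj))),
        "c5": not any(m and 10 <= p <= 11
                      for m, p in zip(mmlike, positions)),
        "c6": sum((1.0 if m else 0.5 if s == "GU" else 0.0)
                  for m, s, r in zip(mmlike, states, in_region)
                  if r) <= 2.5,
    }
    v["pass"] = all(v.values())
    return v


def bf_scan(mirna: str, transcript: str, max_gaps: int = 1):
    """Exhaustive window enumeration; returns collapsed passing sites as
    (start, end, score) tuples with 1-based inclusive coordinates."""
    L, T = len(mirna), len(transcript)
    lengths = [L] + ([L + 1, L - 1] if max_gaps >= 1 else [])
    passing = []
    for wlen in lengths:
        for s0 in range(T - wlen + 1):
            window = transcript[s0 : s0 + wlen]
            states, positions = bf_best_placement(mirna, window)
            if bf_verdict(mirna, states, positions)["pass"]:
                passing.append((s0 + 1, s0 + wlen, bf_score(states)))
    # collapse overlap-connected clusters to (score, start, end)-minimal
    passing.sort(key=lambda t: (t[0], t[1]))
    collapsed, cluster, cur_end = [], [], None
    for site in passing:
        if cluster and site[0] <= cur_end:
            cluster.append(site)
            cur_end = max(cur_end, site[1])
        else:
            if cluster:
                collapsed.append(min(cluster, key=lambda t: (t[2], t[0], t[1])))
            cluster, cur_end = [site], site[1]
    if cluster:
        collapsed.append(min(cluster, key=lambda t: (t[2], t[0], t[1])))
    return collapsed


def bf_tom(adjacency) -> list[list[float]]:
    """Triple-loop topological overlap from the printed formula."""
    n = len(adjacency)
    a = [[float(adjacency[i][j]) for j in range(n)] for i in range(n)]
    t = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i][j] = 1.0
                continue
            l_ij = sum(a[i][u] * a[u][j] for u in range(n) if u != i and u != j)
            k_i = sum(a[i][u] for u in range(n) if u != i)
            k_j = sum(a[j][u] for u in range(n) if u != j)
            t[i][j] = (l_ij + a[i][j]) / (min(k_i, k_j) + 1 - a[i][j])
    return t


def bf_hypergeom_upper(N: int, n: int, M: int, m: int,
                       background=None) -> float:
    """P(at least m annotated in n draws) by exhaustive enumeration."""
    universe = list(range(N))
    annotated = set(range(M))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(annotated.intersection(draw)) >= m:
            hits += 1
    return hits / total
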