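"""Plant miRNA target prediction by duplex alignment with positional rules.

A candidate site is a transcript window paired against the miRNA read 5'->3',
with the window read 3'->5'.  Each miRNA position receives a pairing state:

* ``WC``  -- Watson-Crick pair (A:U, G:C)
* ``GU``  -- G:U wobble, penalized as half a mismatch
* ``MM``  -- mismatch
* ``GAP`` -- bulged/unpaired nucleotide (at most one per duplex by default)

The alignment score is ``#MM + 0.5 * #GU + #GAP``.  A site passes when all six
screening criteria hold:

1. duplex binding energy >= 74% of the perfect-complement duplex (MFE ratio);
2. score <= 4;
3. at most 2 adjacent-mismatch pairs anywhere in the duplex;
4. no adjacent mismatches within miRNA positions 2-12;
5. no mismatch at miRNA positions 10-11 (the cleavage-defining pair);
6. weighted mismatches within positions 2-12 <= 2.5 (G:U counts 0.5).

Gaps count as mismatches for the positional rules (3-6).  Positions are
1-based from the miRNA 5' end; a transcript-side bulge falls between two miRNA
positions and is assigned the half-integer position in between, so a bulge
inside the 2-12 (or 10-11) span is caught by the span rules.

The per-pair energies behind the MFE ratio are stacking-free: G:C = -3,
A:U = -2, G:U = -1, MM/GAP = 0 (arbitrary units; the criterion is a ratio and
insensitive to affine rescaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequtil import MatureMiRNA, to_rna

WC, GU, MM, GAP = 0, 1, 2, 3
STATE_CHARS = {WC: "|", GU: "o", MM: "x", GAP: "-"}

_BASES = "ACGU"
_B2I = {b: i for i, b in enumerate(_BASES)}

# pair class lookup: rows = miRNA base, cols = transcript base (both ACGU)
_PAIR_CLASS = np.full((4, 4), MM, dtype=np.int8)
for _m, _t in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
    _PAIR_CLASS[_B2I[_m], _B2I[_t]] = WC
for _m, _t in [("G", "U"), ("U", "G")]:
    _PAIR_CLASS[_B2I[_m], _B2I[_t]] = GU

# energy of a Watson-Crick pair, indexed by the miRNA base
_WC_ENERGY = np.array([-2.0, -3.0, -3.0, -2.0])  # A, C, G, U
_GU_ENERGY = -1.0

MFE_THRESHOLD = 74.0
SCORE_THRESHOLD = 4.0
REGION_START, REGION_END = 2, 12
CLEAVAGE_START, CLEAVAGE_END = 10, 11
REGION_WEIGHT_THRESHOLD = 2.5
MAX_ADJACENT_PAIRS = 2


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as an int array (A=0, C=1, G=2, U=3)."""
    seq = to_rna(seq)
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return np.array([_B2I[b] for b in seq], dtype=np.int64)


@dataclass(frozen=True)
class DuplexAlignment:
    """Pairing of one miRNA against one transcript window.

    ``states`` run along the duplex in miRNA 5'->3' order; ``positions`` give
    the miRNA position of each state (half-integers mark transcript bulges).
    ``start``/``end`` are 1-based inclusive transcript coordinates.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    mirna_seq: str
    window_seq: str
    states: tuple[int, ...]
    positions: tuple[float, ...]

    @property
    def score(self) -> float:
        s = self.states
        return s.count(MM) + 0.5 * s.count(GU) + s.count(GAP)

    @property
    def duplex_string(self) -> str:
        return "".join(STATE_CHARS[s] for s in self.states)

    def mirna_base_at(self, k: int) -> str | None:
        pos = self.positions[k]
        if pos != int(pos):
            return None  # transcript bulge, no miRNA base
        return self.mirna_seq[int(pos) - 1]


@dataclass(frozen=True)
class CriteriaVerdict:
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool

    @property
    def passed(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4 and self.c5 and self.c6

    def as_tuple(self) -> tuple[bool, ...]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6)


def _pair_states(m: np.ndarray, w: np.ndarray, skip_window: int | None,
                 skip_mirna: int | None) -> tuple[list[int], list[float]]:
    """States + miRNA positions for one placement.

    ``skip_window``: 0-based window index left unpaired (transcript bulge);
    ``skip_mirna``: 0-based miRNA index left unpaired (miRNA-side gap).
    Exactly one of them may be set; pairing runs miRNA 5'->3' against
    descending window indices.
    """
    L = len(m)
    states: list[int] = []
    positions: list[float] = []
    widx = len(w) - 1
    i = 0
    while i < L or widx >= 0:
        if skip_mirna is not None and i == skip_mirna:
            states.append(GAP)
            positions.append(float(i + 1))
            i += 1
            continue
        if skip_window is not None and widx == skip_window:
            states.append(GAP)
            positions.append(i + 0.5)  # between miRNA positions i and i+1
            widx -= 1
            continue
        states.append(int(_PAIR_CLASS[m[i], w[widx]]))
        positions.append(float(i + 1))
        i += 1
        widx -= 1
    return states, positions


def align_duplex(mirna: MatureMiRNA | str, window: str, max_gaps: int = 1,
                 mirna_id: str = "", transcript_id: str = "",
                 start: int = 1) -> DuplexAlignment:
    """Align a miRNA against one transcript window.

    The window length must be within ``max_gaps`` of the miRNA length; the
    length difference fixes the number and side of GAP states (longer window:
    transcript bulge; shorter: unpaired miRNA position).  Among all gap
    placements the one maximizing the Watson-Crick pair count wins, ties going
    to the leftmost gap in duplex (miRNA 5'->3') order.  Only ``max_gaps <= 1``
    is supported.
    """
    if max_gaps > 1:
        raise NotImplementedError("max_gaps > 1 is not supported")
    if isinstance(mirna, MatureMiRNA):
        mirna_id = mirna_id or mirna.id
        mseq = mirna.sequence
    else:
        mseq = to_rna(mirna)
    wseq = to_rna(window)
    L, W = len(mseq), len(wseq)
    if not (L - max_gaps <= W <= L + max_gaps):
        raise ValueError(
            f"window length {W} outside miRNA length {L} +/- {max_gaps}"
        )
    m, w = encode(mseq), encode(wseq)

    if W == L:
        placements = [_pair_states(m, w, None, None)]
    elif W == L + 1:
        # transcript bulge: leftmost gap in duplex order = highest window index
        placements = [_pair_states(m, w, j, None) for j in range(W - 1, -1, -1)]
    else:
        placements = [_pair_states(m, w, None, g) for g in range(L)]
    best = max(placements, key=lambda sp: sp[0].count(WC))
    # max() keeps the first of ties, which is the leftmost gap by construction
    states, positions = best
    return DuplexAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        start=start,
        end=start + W - 1,
        mirna_seq=mseq,
        window_seq=wseq,
        states=tuple(states),
        positions=tuple(positions),
    )


def duplex_energy(duplex: DuplexAlignment) -> float:
    """Stacking-free binding energy of the duplex (arbitrary units, <= 0)."""
    e = 0.0
    for k, s in enumerate(duplex.states):
        if s == WC:
            e += _WC_ENERGY[_B2I[duplex.mirna_base_at(k)]]
        elif s == GU:
            e += _GU_ENERGY
    return e


def perfect_energy(mirna_seq: str) -> float:
    """Energy of the perfect-complement duplex of the miRNA."""
    return float(sum(_WC_ENERGY[_B2I[b]] for b in to_rna(mirna_seq)))


def mfe_ratio(duplex: DuplexAlignment) -> float:
    """Duplex binding energy as a percentage of the perfect duplex (0-100)."""
    e_perfect = perfect_energy(duplex.mirna_seq)
    if e_perfect == 0:
        raise ValueError("degenerate empty miRNA: perfect duplex energy is 0")
    return 100.0 * duplex_energy(duplex) / e_perfect


def apply_criteria(duplex: DuplexAlignment) -> CriteriaVerdict:
    """Evaluate the six screening criteria on an aligned duplex."""
    states = duplex.states
    pos = duplex.positions
    mmlike = [s in (MM, GAP) for s in states]

    adj_pairs = sum(1 for k in range(len(states) - 1) if mmlike[k] and mmlike[k + 1])
    in_region = [REGION_START <= p <= REGION_END for p in pos]
    adj_in_region = any(
        mmlike[k] and mmlike[k + 1] and in_region[k] and in_region[k + 1]
        for k in range(len(states) - 1)
    )
    at_cleavage = any(
        mmlike[k] and CLEAVAGE_START <= pos[k] <= CLEAVAGE_END
        for k in range(len(states))
    )
    region_weight = sum(
        (1.0 if mmlike[k] else 0.5 if states[k] == GU else 0.0)
        for k in range(len(states))
        if in_region[k]
    )

    return CriteriaVerdict(
        c1=mfe_ratio(duplex) >= MFE_THRESHOLD,
        c2=duplex.score <= SCORE_THRESHOLD,
        c3=adj_pairs <= MAX_ADJACENT_PAIRS,
        c4=not adj_in_region,
        c5=not at_cleavage,
        c6=region_weight <= REGION_WEIGHT_THRESHOLD,
    )


def cleavage_position(duplex: DuplexAlignment) -> int:
    """Transcript coordinate paired with miRNA position 10 (1-based).

    With the window read 3'->5' against the miRNA, miRNA position ``p`` pairs
    transcript position ``end - (p - 1) - n_bulges_5prime``, where bulges
    between the window 3' end and the pair shift the coordinate.
    """
    # walk the duplex, tracking the transcript index from the window 3' end
    widx = len(duplex.window_seq) - 1
    for k, s in enumerate(duplex.states):
        p = duplex.positions[k]
        if s == GAP and p != int(p):
            widx -= 1  # transcript bulge consumes a window base
            continue
        if p == 10:
            # unpaired miRNA position 10 (GAP) has no paired base; the next
            # unconsumed window base stands in (such duplexes fail c5 anyway)
            return duplex.start + widx
        if s != GAP:
            widx -= 1
    raise ValueError("miRNA shorter than 10 nt has no cleavage position")


# ---------------------------------------------------------------------------
# vectorized transcript scanning


def _criteria_matrix(states: np.ndarray, positions: np.ndarray,
                     m: np.ndarray, e_perfect: float) -> dict[str, np.ndarray]:
    """Vectorized score/criteria for a block of windows.

    ``states``: (n_states, n_windows) pairing classes; ``positions``:
    (n_states,) miRNA positions (half-integers for transcript bulges);
    ``m``: encoded miRNA.  Returns per-window arrays.
    """
    is_mm = states == MM
    is_gu = states == GU
    is_gap = states == GAP
    mmlike = is_mm | is_gap

    score = is_mm.sum(0) + 0.5 * is_gu.sum(0) + is_gap.sum(0)

    adj = mmlike[:-1] & mmlike[1:]
    adj_pairs = adj.sum(0)

    in_region = (positions >= REGION_START) & (positions <= REGION_END)
    adj_region = (adj & (in_region[:-1] & in_region[1:])[:, None]).any(0)
    at_cleavage = (
        mmlike & ((positions >= CLEAVAGE_START) & (positions <= CLEAVAGE_END))[:, None]
    ).any(0)
    region_weight = (
        np.where(mmlike, 1.0, np.where(is_gu, 0.5, 0.0)) * in_region[:, None]
    ).sum(0)

    # energy: WC pairs contribute the miRNA-base energy, GU contributes -1
    int_pos = positions == np.floor(positions)
    base_energy = np.zeros(len(positions))
    base_energy[int_pos] = _WC_ENERGY[m[positions[int_pos].astype(int) - 1]]
    energy = (is_gu * _GU_ENERGY + (states == WC) * base_energy[:, None]).sum(0)
    ratio = 100.0 * energy / e_perfect

    passed = (
        (ratio >= MFE_THRESHOLD)
        & (score <= SCORE_THRESHOLD)
        & (adj_pairs <= MAX_ADJACENT_PAIRS)
        & ~adj_region
        & ~at_cleavage
        & (region_weight <= REGION_WEIGHT_THRESHOLD)
    )
    return {"score": score, "ratio": ratio, "passed": passed}


def _scan_ungapped(m: np.ndarray, t: np.ndarray, e_perfect: float):
    L, T = len(m), len(t)
    if T < L:
        return np.empty(0, dtype=int), {}
    starts = np.arange(T - L + 1)
    i = np.arange(L)
    cols = starts[None, :] + (L - 1 - i)[:, None]
    states = _PAIR_CLASS[m[:, None], t[cols]].astype(np.int8)
    res = _criteria_matrix(states, i + 1.0, m, e_perfect)
    return starts, res


def _scan_bulged(m: np.ndarray, t: np.ndarray, e_perfect: float):
    """Windows of length L+1 with one transcript bulge."""
    L, T = len(m), len(t)
    W = L + 1
    if T < W:
        return np.empty(0, dtype=int), {}
    starts = np.arange(T - W + 1)
    i = np.arange(L)
    all_scores, all_ratios, all_passed, all_wc = [], [], [], []
    # placements ordered leftmost-gap-first in duplex order: j = W-1 down to 0
    for j in range(W - 1, -1, -1):
        # miRNA i pairs window index w = L - i (if i < L - j) else L - 1 - i
        w_idx = np.where(i < L - j, L - i, L - 1 - i)
        cols = starts[None, :] + w_idx[:, None]
        paired = _PAIR_CLASS[m[:, None], t[cols]].astype(np.int8)
        k_gap = L - j  # state index of the inserted GAP
        states = np.insert(paired, k_gap, GAP, axis=0)
        positions = np.insert(i + 1.0, k_gap, (L - j) + 0.5)
        res = _criteria_matrix(states, positions, m, e_perfect)
        all_wc.append((states == WC).sum(0))
        all_scores.append(res["score"])
        all_ratios.append(res["ratio"])
        all_passed.append(res["passed"])
    wc = np.stack(all_wc)
    best = wc.argmax(0)  # first max = leftmost gap
    take = lambda arrs: np.stack(arrs)[best, np.arange(len(starts))]
    return starts, {
        "score": take(all_scores),
        "ratio": take(all_ratios),
        "passed": take(all_passed),
    }


def _scan_mirna_gapped(m: np.ndarray, t: np.ndarray, e_perfect: float):
    """Windows of length L-1 with one unpaired miRNA position."""
    L, T = len(m), len(t)
    W = L - 1
    if T < W or W < 1:
        return np.empty(0, dtype=int), {}
    starts = np.arange(T - W + 1)
    i = np.arange(L)
    all_scores, all_ratios, all_passed, all_wc = [], [], [], []
    for g in range(L):  # leftmost-gap-first: g ascending
        rank = np.where(i < g, i, i - 1)
        w_idx = (W - 1) - rank  # valid where i != g
        cols = starts[None, :] + np.clip(w_idx, 0, W - 1)[:, None]
        states = _PAIR_CLASS[m[:, None], t[cols]].astype(np.int8)
        states[g, :] = GAP
        positions = i + 1.0
        res = _criteria_matrix(states, positions, m, e_perfect)
        all_wc.append((states == WC).sum(0))
        all_scores.append(res["score"])
        all_ratios.append(res["ratio"])
        all_passed.append(res["passed"])
    wc = np.stack(all_wc)
    best = wc.argmax(0)
    take = lambda arrs: np.stack(arrs)[best, np.arange(len(starts))]
    return starts, {
        "score": take(all_scores),
        "ratio": take(all_ratios),
        "passed": take(all_passed),
    }


def _collapse(sites: list[dict]) -> list[dict]:
    """Collapse overlapping passing windows of one (miRNA, transcript) pair.

    Overlap-connected clusters keep the best-scoring window (ties: lowest
    score, then smallest start).
    """
    if not sites:
        return []
    sites = sorted(sites, key=lambda s: (s["start"], s["end"]))
    clusters: list[list[dict]] = [[sites[0]]]
    cur_end = sites[0]["end"]
    for s in sites[1:]:
        if s["start"] <= cur_end:
            clusters[-1].append(s)
            cur_end = max(cur_end, s["end"])
        else:
            clusters.append([s])
            cur_end = s["end"]
    return [min(c, key=lambda s: (s["score"], s["start"], s["end"])) for c in clusters]


PREDICTION_COLUMNS = [
    "mirna_id", "transcript_id", "start", "end", "score", "mfe_ratio",
    "c1", "c2", "c3", "c4", "c5", "c6", "pass", "duplex", "cleavage_pos",
]


def predict_targets(
    mirnas: dict[str, str] | list[MatureMiRNA],
    transcripts: dict[str, str],
    max_gaps: int = 1,
) -> pd.DataFrame:
    """Scan transcripts for miRNA target sites passing all six criteria.

    Every window of length (miRNA length +/- ``max_gaps``) is aligned at step
    1; passing sites are reported, with overlapping passing windows of one
    (miRNA, transcript) pair collapsed to the best-scoring one.  Returns a
    table with one row per retained site.
    """
    if isinstance(mirnas, list):
        mirnas = {mi.id: mi.sequence for mi in mirnas}
    if not mirnas or not transcripts:
        raise ValueError("empty miRNA or transcript input")

    rows = []
    for mid, mseq in mirnas.items():
        mseq = to_rna(mseq)
        m = encode(mseq)
        L = len(m)
        e_perfect = perfect_energy(mseq)
        for tid, tseq in transcripts.items():
            tseq = to_rna(tseq)
            t = encode(tseq)
            passing: list[dict] = []
            scans = [(_scan_ungapped, L)]
            if max_gaps >= 1:
                scans += [(_scan_bulged, L + 1), (_scan_mirna_gapped, L - 1)]
            for fn, wlen in scans:
                starts, res = fn(m, t, e_perfect)
                if len(starts) == 0:
                    continue
                for s0 in starts[res["passed"]]:
                    passing.append(
                        {"start": int(s0) + 1, "end": int(s0) + wlen,
                         "score": float(res["score"][s0]),
                         "wlen": wlen}
                    )
            for site in _collapse(passing):
                window = tseq[site["start"] - 1 : site["end"]]
                dup = align_duplex(mseq, window, max_gaps=max_gaps,
                                   mirna_id=mid, transcript_id=tid,
                                   start=site["start"])
                verdict = apply_criteria(dup)
                rows.append(
                    {
                        "mirna_id": mid,
                        "transcript_id": tid,
                        "start": dup.start,
                        "end": dup.end,
                        "score": dup.score,
                        "mfe_ratio": mfe_ratio(dup),
                        **{f"c{k + 1}": v for k, v in enumerate(verdict.as_tuple())},
                        "pass": verdict.passed,
                        "duplex": dup.duplex_string,
                        "cleavage_pos": cleavage_position(dup),
                    }
                )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
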