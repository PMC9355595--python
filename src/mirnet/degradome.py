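"""Degradome (PARE) cleavage-site validation of predicted miRNA targets.

Degradome sequencing captures the uncapped 5' ends of cleaved mRNAs; a miRNA-
guided cleavage leaves a tag pile-up at the transcript position paired with
miRNA position 10.  A predicted site is validated by classifying the tag
abundance at its expected cleavage position relative to the rest of the
transcript, using the five-category convention of prediction-guided degradome
pipelines:

* category 0 -- site count equals the transcript maximum, uniquely attained
* category 1 -- site count equals a maximum shared by several positions
* category 2 -- above the median of nonzero positions, below the maximum
* category 3 -- more than one read but at or below that median
* category 4 -- exactly one read

Sites with zero reads get no category ("no call").  By default only
categories 0-2 are kept as true targets, and a kept site must additionally
have duplex score <= 4 and no mismatch at miRNA positions 10-11.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DegradomeProfile:
    """Per-position 5'-end tag counts on one transcript (1-based positions)."""

    transcript_id: str
    length: int
    counts: np.ndarray  # shape (length,), counts[i] = reads starting at i+1

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if len(c) != self.length:
            raise ValueError("counts length != transcript length")
        if (c < 0).any():
            raise ValueError("negative degradome counts")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def at(self, position: int) -> int:
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside transcript "
                f"{self.transcript_id} (length {self.length})"
            )
        return int(self.counts[position - 1])


def build_profile(tags: pd.DataFrame, transcript_id: str, length: int) -> DegradomeProfile:
    """Sum 5'-end tag counts per position for one transcript.

    ``tags`` needs columns ``transcript_id``, ``position`` (1-based) and
    ``count``; rows for other transcripts are ignored.  Positions outside the
    transcript raise, naming the offending record.
    """
    counts = np.zeros(length, dtype=np.int64)
    sub = tags[tags["transcript_id"] == transcript_id]
    for row in sub.itertuples(index=False):
        pos = int(row.position)
        if not 1 <= pos <= length:
            raise ValueError(
                f"degradome tag at position {pos} outside transcript "
                f"{transcript_id} (length {length})"
            )
        counts[pos - 1] += int(row.count)
    return DegradomeProfile(transcript_id, length, counts)


def build_profiles(tags: pd.DataFrame, lengths: dict[str, int]) -> dict[str, DegradomeProfile]:
    """Build one profile per transcript in ``lengths``."""
    return {tid: build_profile(tags, tid, ln) for tid, ln in lengths.items()}


def classify_category(profile: DegradomeProfile, position: int) -> int | None:
    """Five-category abundance class of the site count within its transcript.

    Returns ``None`` (no call) for a zero count or an all-zero profile; the
    median is taken over nonzero positions only, since degradome profiles are
    sparse and a position-wide median would almost always be zero.
    """
    counts = profile.counts
    nonzero = counts[counts > 0]
    if len(nonzero) == 0:
        return None
    s = profile.at(position)
    if s == 0:
        return None
    if s == 1:
        return 4
    maximum = int(counts.max())
    median = float(np.median(nonzero))
    if s == maximum:
        return 0 if (counts == maximum).sum() == 1 else 1
    if s > median:
        return 2
    return 3


KEEP_CATEGORY_DEFAULT = 2

CALL_COLUMNS = [
    "mirna_id", "transcript_id", "cleavage_pos", "score", "site_count",
    "max_count", "median_nonzero", "category", "kept",
]


def validate_targets(
    predictions: pd.DataFrame,
    profiles: dict[str, DegradomeProfile],
    keep_category: int = KEEP_CATEGORY_DEFAULT,
    score_threshold: float = 4.0,
    position_tolerance: int = 0,
) -> pd.DataFrame:
    """Classify degradome support at each predicted site and call true targets.

    The expected cleavage position is the transcript coordinate paired with
    miRNA position 10 (column ``cleavage_pos`` of the prediction table).  A
    call is kept when category <= ``keep_category``, duplex score <=
    ``score_threshold`` and the prediction has no mismatch at miRNA positions
    10-11 (prediction criterion 5).  With ``position_tolerance`` = n > 0 the
    best-supported position within +/- n nt of the expected one is used
    (off by default: strict position match).

    Predictions whose transcript has no profile are reported with category
    ``None`` and ``kept = False``.
    """
    rows = []
    for pred in predictions.itertuples(index=False):
        profile = profiles.get(pred.transcript_id)
        pos = int(pred.cleavage_pos)
        if profile is None:
            rows.append(
                dict(mirna_id=pred.mirna_id, transcript_id=pred.transcript_id,
                     cleavage_pos=pos, score=pred.score, site_count=0,
                     max_count=0, median_nonzero=0.0, category=None, kept=False)
            )
            continue
        if position_tolerance > 0:
            lo = max(1, pos - position_tolerance)
            hi = min(profile.length, pos + position_tolerance)
            window = range(lo, hi + 1)
            pos = max(window, key=lambda p: (profile.at(p), -abs(p - int(pred.cleavage_pos))))
        category = classify_category(profile, pos)
        nonzero = profile.counts[profile.counts > 0]
        kept = (
            category is not None
            and category <= keep_category
            and pred.score <= score_threshold
            and bool(pred.c5)
        )
        rows.append(
            dict(
                mirna_id=pred.mirna_id,
                transcript_id=pred.transcript_id,
                cleavage_pos=pos,
                score=pred.score,
                site_count=profile.at(pos),
                max_count=int(profile.counts.max()),
                median_nonzero=float(np.median(nonzero)) if len(nonzero) else 0.0,
                category=category,
                kept=kept,
            )
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
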