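"""Sequence I/O, small-RNA tag filtering, and known-miRNA family assignment.

Sequences are held internally in the RNA alphabet (``ACGU``); FASTA files are
written in the DNA alphabet (``ACGT``), matching the dialect most mature-miRNA
and transcript FASTA files use.  The U/T conversion is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = set("ACGU")

# raw reads may carry ambiguous bases before the high-N screen removes them
RAW_ALPHABET = RNA_ALPHABET | {"N"}

#: defect flags a read can carry; any flag disqualifies the read
TAG_FLAGS = frozenset(
    {
        "low_quality",
        "high_N",
        "adapter5_contaminated",
        "no_adapter3",
        "polyA",
        "out_of_length_range",
    }
)

#: retained small-RNA length band, inclusive
MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


def to_rna(seq: str) -> str:
    """Normalize a sequence to the uppercase RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Normalize a sequence to the uppercase DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(seq))


@dataclass(frozen=True)
class SmallRNATag:
    """A deduplicated small-RNA sequence tag with per-library counts."""

    sequence: str
    counts: tuple[tuple[str, int], ...] = ()
    flags: frozenset[str] = frozenset()
    id: str | None = None

    def count_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.counts)

    def is_clean(self) -> bool:
        return not self.flags and MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN


@dataclass(frozen=True)
class MatureMiRNA:
    """A known mature miRNA with its family label (miRBase-style)."""

    id: str
    family: str
    sequence: str

    def __post_init__(self):
        norm = to_rna(self.sequence)
        object.__setattr__(self, "sequence", norm)
        bad = set(norm) - RNA_ALPHABET
        if bad:
            raise ValueError(f"miRNA {self.id}: invalid characters {sorted(bad)}")


def make_tag(sequence: str, counts: dict[str, int] | None = None,
             flags: set[str] | None = None, id: str | None = None) -> SmallRNATag:
    """Convenience constructor normalizing the sequence to RNA."""
    flags = frozenset(flags or ())
    unknown = flags - TAG_FLAGS
    if unknown:
        raise ValueError(f"unknown flags: {sorted(unknown)}")
    return SmallRNATag(
        sequence=to_rna(sequence),
        counts=tuple(sorted((counts or {}).items())),
        flags=flags,
        id=id,
    )


def filter_tags(tags: list[SmallRNATag]) -> list[SmallRNATag]:
    """Quality-screen and deduplicate small-RNA tags.

    Removes reads carrying any defect flag (bases below Q20, >5% N, 5' adapter
    contamination, missing 3' adapter, polyA tail) and sequences outside the
    18-30 nt band, then merges identical sequences by summing their per-library
    counts.  Returns tags sorted by sequence for reproducibility.
    """
    bad_ids = [
        t.id or f"<record {i}>"
        for i, t in enumerate(tags)
        if set(t.sequence) - RAW_ALPHABET
    ]
    if bad_ids:
        raise ValueError(f"malformed sequence characters in records: {bad_ids}")

    merged: dict[str, dict[str, int]] = {}
    for t in tags:
        if not t.is_clean():
            continue
        lib_counts = merged.setdefault(t.sequence, {})
        for lib, c in t.counts:
            lib_counts[lib] = lib_counts.get(lib, 0) + c
    return [
        SmallRNATag(sequence=s, counts=tuple(sorted(merged[s].items())))
        for s in sorted(merged)
    ]


def _lcs_length(a: str, b: str) -> int:
    """Longest common (contiguous) substring length by dynamic programming."""
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _best_ungapped_mismatches(tag: str, known: str) -> int:
    """Fewest mismatches over ungapped alignments covering the shorter sequence."""
    short, long_ = (tag, known) if len(tag) <= len(known) else (known, tag)
    best = len(short) + 1
    for off in range(len(long_) - len(short) + 1):
        mm = sum(1 for a, b in zip(short, long_[off : off + len(short)]) if a != b)
        best = min(best, mm)
    return best


def assign_family(
    tag: SmallRNATag,
    known: list[MatureMiRNA],
    max_mismatches: int = 1,
    min_overlap: int = 16,
) -> str | None:
    """Assign a tag to a known miRNA family.

    A tag joins the family of a known mature miRNA when its best ungapped
    alignment against that miRNA has at most ``max_mismatches`` substitutions
    ("less than two mismatches"), or when the two sequences share an exact
    contiguous block of at least ``min_overlap`` nt.  Among several qualifying
    miRNAs the winner has the fewest mismatches, then the longest exact
    overlap, then the lexicographically smallest family id.
    """
    candidates = []
    for k in known:
        mm = _best_ungapped_mismatches(tag.sequence, k.sequence)
        ov = _lcs_length(tag.sequence, k.sequence)
        if mm <= max_mismatches or ov >= min_overlap:
            candidates.append((mm, -ov, k.family))
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][2]


def read_fasta(path: str | Path, alphabet: str = "rna") -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased and converted to the requested alphabet
    (``"rna"`` or ``"dna"``).  Duplicate record ids raise ``ValueError``.
    """
    conv = to_rna if alphabet == "rna" else to_dna
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = conv(str(rec.seq))
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write sequences as DNA-alphabet FASTA (U converted to T)."""
    recs = [
        SeqRecord(Seq(to_dna(seq)), id=rid, description="")
        for rid, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def flag_fastq(path: str | Path) -> list[SmallRNATag]:
    """Minimal FASTQ flagger: marks reads with any base below Q20 or >5% N.

    Adapter-related defects cannot be derived from a bare FASTQ and must be
    supplied as precomputed flags; this helper covers only the quality rules.
    Each read becomes a tag with count 1 in a library named after the file stem.
    """
    lib = Path(path).stem
    tags = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        quals = rec.letter_annotations["phred_quality"]
        flags: set[str] = set()
        if any(q < 20 for q in quals):
            flags.add("low_quality")
        if seq and seq.count("N") / len(seq) > 0.05:
            flags.add("high_N")
        tags.append(make_tag(to_rna(seq), {lib: 1}, flags, id=rec.id))
    return tags
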