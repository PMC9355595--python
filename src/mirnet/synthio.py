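"""Synthetic data generation for the whole miRNA-mRNA analysis pipeline.

The generator emulates the data structure of a four-stage (three replicates
each) floral-bud developmental series:

* a gene expression matrix with block-correlated planted co-expression
  modules (genes of one module share a latent per-sample factor, giving
  pairwise correlations near ``within_module_cor`` on the log scale), one
  module tied to a per-sample trait (bud break rate proxy);
* negative-binomial counts around FPKM-derived means, with a designated
  subset of genes carrying a planted log2 fold change between two stages;
* miRNA/transcript sequence pairs with planted duplex sites of controlled
  mismatch / G:U / position patterns, whose criterion compliance is computed
  by literal application of the screening rules (independently of the
  prediction code, so the two can be cross-checked);
* degradome tag profiles with 5'-end peaks at the expected cleavage sites of
  compliant planted sites over a Poisson background.

All generators are deterministic given the configuration seed.  The bundle
generator threads a single seeded stream through the stages in a fixed,
documented order (expression -> miRNA expression -> sequences/sites ->
degradome -> annotation); called standalone, each generator derives its own
stream from the seed so results are reproducible in isolation as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .enrich import TermAnnotation, write_annotations
from .quant import ExpressionMatrix
from .sequtil import revcomp_rna, write_fasta

DEFAULT_STAGES = ("EndodorI", "EndodorII", "Ecodor", "BFlush")

#: transcription-factor family vocabulary used for synthetic TF annotation
TF_FAMILIES = ("MADS", "AP2/ERF", "HD-ZIP", "SBP", "GRAS", "TCP", "MYB",
               "NAC", "ARF", "GRF")

_GC = {"G", "C"}
_PAIR_ENERGY = {"A": 2.0, "U": 2.0, "G": 3.0, "C": 3.0}  # magnitudes


@dataclass(frozen=True)
class SiteSpec:
    """One planted duplex site: where it goes and which defects it carries.

    ``position`` is the 1-based transcript coordinate of the site window
    start; ``mismatch_positions`` and ``gu_positions`` are 1-based miRNA
    positions (5' end = 1).
    """

    mirna_id: str
    transcript_id: str
    position: int
    mismatch_positions: tuple[int, ...] = ()
    gu_positions: tuple[int, ...] = ()
    peak_height: int | None = None


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Defaults mirror the emulated study design: 4 stages x 3 replicates,
    600 genes of which 150 are module-free noise, three planted modules with
    within-module correlation 0.8, the first module trait-associated, a
    planted 4-fold (log2FC = 2) effect between the first two stages, and
    negative-binomial dispersion 0.05 (library sizes and dispersion are
    conventional bulk-RNA-seq values, not study-derived).
    """

    seed: int = 0
    n_genes: int = 600
    n_mirnas: int = 150
    stages: tuple[str, ...] = DEFAULT_STAGES
    reps_per_stage: int = 3
    n_modules: int = 3
    within_module_cor: float = 0.8
    trait_module_index: int = 0
    n_noise_genes: int = 150
    n_de_genes: int = 50
    n_de_mirnas: int = 8
    de_effect_log2fc: float = 2.0
    mirna_de_effect_log2fc: float = 3.0
    de_stage_pair: tuple[int, int] = (0, 1)
    nb_dispersion: float = 0.05
    transcript_length_range: tuple[int, int] = (800, 1200)
    mirna_length: int = 21
    hub_loading: float | None = None
    planted_site_spec: tuple[SiteSpec, ...] | None = None
    n_planted_sites: int = 8
    degradome_peak_height: int = 50
    degradome_noise_rate: float = 0.05
    trait_noise_fraction: float = 0.1

    def __post_init__(self):
        if min(self.n_genes, self.n_mirnas, self.reps_per_stage,
               self.n_modules, len(self.stages)) <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 <= self.within_module_cor <= 1:
            raise ValueError("within_module_cor must be in [0, 1]")
        if not 0 <= self.trait_module_index < self.n_modules:
            raise ValueError("trait_module_index must be < n_modules")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_noise_genes >= self.n_genes:
            raise ValueError("n_noise_genes must be < n_genes")
        if self.degradome_noise_rate < 0:
            raise ValueError("degradome_noise_rate must be >= 0")
        if self.hub_loading is not None and not 0 < self.hub_loading <= 1:
            raise ValueError("hub_loading must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.stages) * self.reps_per_stage

    def sample_table(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{st}_{r}", "stage": st, "replicate": r}
            for st in self.stages
            for r in range(1, self.reps_per_stage + 1)
        ]
        return pd.DataFrame(rows).set_index("sample")


class ExpressionSim(NamedTuple):
    counts: ExpressionMatrix
    fpkm: ExpressionMatrix
    trait: pd.Series
    truth: pd.DataFrame  # gene, module (int, -1 = noise), is_de
    factors: pd.DataFrame  # samples x modules latent factors


def _rng(config: SimConfig, stream: int, rng: np.random.Generator | None):
    if rng is not None:
        return rng
    return np.random.default_rng([config.seed, stream])


def simulate_expression(config: SimConfig,
                        rng: np.random.Generator | None = None) -> ExpressionSim:
    """Simulate counts, FPKM and a trait with planted module structure.

    Generation order (fixed for reproducibility): module latent factors,
    gene baselines, gene-level noise, gene lengths, library sizes, NB counts,
    trait noise.  Module genes follow ``sqrt(rho) * factor + sqrt(1-rho) *
    noise`` on the log2 scale, giving pairwise correlation ``rho`` =
    ``within_module_cor``.  FPKM is recomputed from the realized counts with
    the true gene lengths and realized library sizes, so downstream
    expression filters see count noise.  The trait equals the trait module's
    factor plus Gaussian noise at ``trait_noise_fraction`` of its SD.
    """
    rng = _rng(config, 1, rng)
    samples = config.sample_table()
    n_s = config.n_samples
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]

    n_module_genes = config.n_genes - config.n_noise_genes
    per_module = n_module_genes // config.n_modules
    module_of = np.full(config.n_genes, -1, dtype=int)
    for m in range(config.n_modules):
        module_of[m * per_module : (m + 1) * per_module] = m

    # latent module factors, orthogonalized: planted modules are independent
    # by design, and at a dozen samples raw Gaussian draws correlate enough
    # by chance to blur the planted block structure
    raw = rng.standard_normal((n_s, config.n_modules))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    factors = q * np.sqrt(n_s - 1)  # unit sample variance, zero pairwise corr
    baseline = rng.uniform(3.0, 8.0, size=config.n_genes)
    noise = rng.standard_normal((config.n_genes, n_s))

    rho = config.within_module_cor
    is_hub = np.zeros(config.n_genes, dtype=bool)
    if config.hub_loading is not None:
        # first gene of each module carries the highest factor loading and a
        # solid baseline: a hub is a well-expressed exemplar of its module,
        # not a gene whose profile drowns in shot noise
        for m in range(config.n_modules):
            is_hub[m * per_module] = True
            baseline[m * per_module] = 7.0
    z = np.empty((config.n_genes, n_s))
    for g in range(config.n_genes):
        m = module_of[g]
        shared = factors[:, m] if m >= 0 else 0.0
        lam = config.hub_loading if is_hub[g] else np.sqrt(rho)
        z[g] = lam * shared + np.sqrt(1 - lam**2) * noise[g]

    log2fpkm = baseline[:, None] + z

    # planted DE effect: first n_de_genes of the noise pool, up in stage b
    noise_idx = np.where(module_of == -1)[0]
    de_idx = noise_idx[: config.n_de_genes]
    is_de = np.zeros(config.n_genes, dtype=bool)
    is_de[de_idx] = True
    stage_b = config.stages[config.de_stage_pair[1]]
    b_cols = np.array([samples.loc[s, "stage"] == stage_b
                       for s in samples.index])
    log2fpkm[np.ix_(de_idx, np.where(b_cols)[0])] += config.de_effect_log2fc

    lengths = rng.integers(config.transcript_length_range[0],
                           config.transcript_length_range[1] + 1,
                           size=config.n_genes)
    libsizes = rng.uniform(8e6, 12e6, size=n_s)

    latent_fpkm = 2.0 ** log2fpkm
    mu = latent_fpkm * (lengths[:, None] / 1e3) * (libsizes[None, :] / 1e6)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    # FPKM from realized counts with the true lengths and library sizes;
    # normalizing by the realized column totals instead would couple every
    # gene to the planted modules (150 of 600 genes swinging two-fold moves
    # the total), an artifact real 20k-gene libraries barely show
    fpkm = counts / (lengths[:, None] / 1e3) / (libsizes[None, :] / 1e6)

    f_trait = factors[:, config.trait_module_index]
    trait = f_trait + rng.normal(
        0.0, config.trait_noise_fraction * f_trait.std(ddof=1), size=n_s)

    counts_em = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples.index),
        samples, "count")
    fpkm_em = ExpressionMatrix(
        pd.DataFrame(fpkm, index=genes, columns=samples.index),
        samples, "FPKM")
    truth = pd.DataFrame(
        {"gene": genes, "module": module_of, "is_de": is_de,
         "is_hub": is_hub, "length": lengths}
    )
    factors_df = pd.DataFrame(
        factors, index=samples.index,
        columns=[f"M{m}" for m in range(config.n_modules)])
    return ExpressionSim(counts_em, fpkm_em,
                         pd.Series(trait, index=samples.index, name="bbr"),
                         truth, factors_df)


# ---------------------------------------------------------------------------
# planted duplex sites


def site_compliance(mirna_seq: str, mismatch_positions: tuple[int, ...],
                    gu_positions: tuple[int, ...]) -> dict:
    """Literal application of the six screening rules to a defect pattern.

    This is deliberately independent of the prediction code: compliance is
    derived from the planted pattern alone (score arithmetic, positional
    rules, and the per-pair energy model), so planted truth labels can act as
    an oracle for the scanner.
    """
    L = len(mirna_seq)
    mm, gu = set(mismatch_positions), set(gu_positions)
    if mm & gu:
        raise ValueError("a position cannot be both mismatch and G:U")
    for p in mm | gu:
        if not 1 <= p <= L:
            raise ValueError(f"pattern position {p} outside miRNA length {L}")
    score = len(mm) + 0.5 * len(gu)
    in_region = lambda p: 2 <= p <= 12
    region_weight = sum(1 for p in mm if in_region(p)) + 0.5 * sum(
        1 for p in gu if in_region(p))
    adj_pairs = sum(1 for p in mm if p + 1 in mm)
    e_perfect = sum(_PAIR_ENERGY[b] for b in mirna_seq)
    removed = sum(_PAIR_ENERGY[mirna_seq[p - 1]] for p in mm) + sum(
        _PAIR_ENERGY[mirna_seq[p - 1]] - 1.0 for p in gu)
    ratio = 100.0 * (e_perfect - removed) / e_perfect
    verdict = {
        "c1": ratio >= 74.0,
        "c2": score <= 4.0,
        "c3": adj_pairs <= 2,
        "c4": not any(p + 1 in mm and in_region(p) and in_region(p + 1)
                      for p in mm),
        "c5": not (mm & {10, 11}),
        "c6": region_weight <= 2.5,
    }
    verdict["compliant"] = all(verdict.values())
    verdict["score"] = score
    verdict["mfe_ratio"] = ratio
    return verdict


def random_rna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate_window(window: list[str], mirna_seq: str, positions: tuple[int, ...],
                   kind: str, rng: np.random.Generator) -> None:
    """Introduce mismatches or G:U wobbles into a perfect-complement window."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    L = len(mirna_seq)
    for p in positions:
        j = L - p  # window index (0-based) pairing miRNA position p
        base = mirna_seq[p - 1]
        if kind == "gu":
            if base == "G":
                window[j] = "U"
            elif base == "U":
                window[j] = "G"
            else:
                raise ValueError(
                    f"G:U wobble impossible at miRNA position {p} (base {base})")
        else:
            forbidden = {comp[base]}
            if base == "G":
                forbidden.add("U")
            elif base == "U":
                forbidden.add("G")
            choices = sorted(set("ACGU") - forbidden)
            window[j] = choices[int(rng.integers(len(choices)))]


TRUTH_COLUMNS = ["mirna_id", "transcript_id", "start", "end", "cleavage_pos",
                 "score", "mfe_ratio", "c1", "c2", "c3", "c4", "c5", "c6",
                 "compliant", "peak_height"]


def simulate_target_sites(
    config: SimConfig,
    mirnas: dict[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Embed planted duplex sites into random background transcripts.

    Each site descriptor places the reverse complement of its miRNA at the
    requested position of the transcript, then introduces the requested
    mismatches and G:U wobbles at the given miRNA positions.  The returned
    truth table records, per site, the literal-rule compliance flags and the
    expected cleavage position (the transcript coordinate pairing miRNA
    position 10).
    """
    rng = _rng(config, 2, rng)
    specs = config.planted_site_spec or ()
    lo, hi = config.transcript_length_range
    transcripts: dict[str, list[str]] = {}
    rows = []
    for spec in specs:
        mseq = mirnas[spec.mirna_id]
        L = len(mseq)
        if spec.transcript_id not in transcripts:
            length = max(int(rng.integers(lo, hi + 1)), spec.position + L + 10)
            transcripts[spec.transcript_id] = list(random_rna(rng, length))
        tseq = transcripts[spec.transcript_id]
        if spec.position + L - 1 > len(tseq):
            raise ValueError(
                f"site at {spec.position} does not fit transcript "
                f"{spec.transcript_id}")
        window = list(revcomp_rna(mseq))
        _mutate_window(window, mseq, spec.mismatch_positions, "mm", rng)
        _mutate_window(window, mseq, spec.gu_positions, "gu", rng)
        tseq[spec.position - 1 : spec.position - 1 + L] = window
        verdict = site_compliance(mseq, spec.mismatch_positions,
                                  spec.gu_positions)
        rows.append(
            {"mirna_id": spec.mirna_id, "transcript_id": spec.transcript_id,
             "start": spec.position, "end": spec.position + L - 1,
             "cleavage_pos": spec.position + L - 10,
             "score": verdict["score"], "mfe_ratio": verdict["mfe_ratio"],
             **{f"c{k}": verdict[f"c{k}"] for k in range(1, 7)},
             "compliant": verdict["compliant"],
             "peak_height": (spec.peak_height if spec.peak_height is not None
                             else config.degradome_peak_height)}
        )
    return (
        {tid: "".join(seq) for tid, seq in transcripts.items()},
        pd.DataFrame(rows, columns=TRUTH_COLUMNS),
    )


def simulate_degradome(
    truth: pd.DataFrame,
    transcripts: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Degradome tag table: peaks at compliant planted cleavage sites plus
    Poisson background noise at ``degradome_noise_rate`` per position."""
    rng = _rng(config, 3, rng)
    rows = []
    for tid in sorted(transcripts):
        length = len(transcripts[tid])
        counts = rng.poisson(config.degradome_noise_rate, size=length)
        sub = truth[(truth["transcript_id"] == tid) & truth["compliant"]]
        for site in sub.itertuples(index=False):
            counts[int(site.cleavage_pos) - 1] += int(site.peak_height)
        for pos in np.nonzero(counts)[0]:
            rows.append({"transcript_id": tid, "position": int(pos) + 1,
                         "count": int(counts[pos])})
    return pd.DataFrame(rows, columns=["transcript_id", "position", "count"])


# ---------------------------------------------------------------------------
# benchmark site sets and annotation


#: defect patterns guaranteed compliant (applied at miRNA length 21)
COMPLIANT_PATTERNS = [
    ((), ()),
    ((3,), ()),
    ((14,), ()),
    ((), (5,)),
    ((3, 16), ()),
    ((5,), (13,)),
    ((13,), (3,)),
    ((4, 15), (8,)),
]

#: single-criterion violator patterns: criterion -> (mm, gu) positions
VIOLATOR_PATTERNS = {
    "c1": ((), (2, 4, 6, 8, 10, 14, 16, 18)),     # 8 wobbles at G bases
    "c2": ((13, 15, 17, 19), (5,)),               # score 4.5
    "c3": ((13, 14, 15, 16), ()),                 # 3 adjacent pairs
    "c4": ((3, 4), ()),                           # adjacent inside 2-12
    "c5": ((10,), ()),                            # cleavage-pair mismatch
    "c6": ((3, 5, 7), ()),                        # 3.0 weighted in 2-12
}


def _mirna_for_pattern(rng: np.random.Generator, length: int,
                       mm: tuple[int, ...], gu: tuple[int, ...],
                       want: str | None) -> str:
    """Draw a miRNA sequence on which the pattern has the intended verdict.

    ``want`` is the single criterion expected to fail (None = fully
    compliant).  G:U positions need a G or U base; base composition is biased
    so the energy criterion lands on the intended side.
    """
    for _ in range(200):
        seq = list(random_rna(rng, length))
        for p in gu:
            # G gives the strongest energy contrast for wobbles
            seq[p - 1] = "G" if want == "c1" else str(
                rng.choice(["G", "U"]))
        if want in ("c2", "c3", "c6"):
            for p in mm:  # weak pairs keep the energy ratio above 74%
                seq[p - 1] = str(rng.choice(["A", "U"]))
        if want == "c1":
            for i in range(length):  # A/U elsewhere keeps |E_perfect| small
                if i + 1 not in gu:
                    seq[i] = str(rng.choice(["A", "U"]))
        v = site_compliance("".join(seq), mm, gu)
        failed = [c for c in ("c1", "c2", "c3", "c4", "c5", "c6")
                  if not v[c]]
        if want is None and not failed:
            return "".join(seq)
        if want is not None and failed == [want]:
            return "".join(seq)
    raise RuntimeError(f"could not realize pattern mm={mm} gu={gu} want={want}")


def planted_site_benchmark(
    rng: np.random.Generator,
    n_compliant: int = 50,
    n_violators: int = 50,
    mirna_length: int = 21,
) -> tuple[dict[str, str], tuple[SiteSpec, ...]]:
    """Build miRNAs and site descriptors for a recovery benchmark.

    ``n_compliant`` sites satisfy all six criteria; ``n_violators`` sites
    each violate exactly one criterion, cycling through the six so every
    criterion is exercised at least ``n_violators // 6`` times.  Each site
    lives on its own transcript.
    """
    mirnas: dict[str, str] = {}
    specs: list[SiteSpec] = []
    viol_keys = sorted(VIOLATOR_PATTERNS)
    for i in range(n_compliant + n_violators):
        if i < n_compliant:
            mm, gu = COMPLIANT_PATTERNS[i % len(COMPLIANT_PATTERNS)]
            want = None
        else:
            key = viol_keys[(i - n_compliant) % len(viol_keys)]
            mm, gu = VIOLATOR_PATTERNS[key]
            want = key
        mid = f"mir{i + 1:03d}"
        mirnas[mid] = _mirna_for_pattern(rng, mirna_length, mm, gu, want)
        pos = int(rng.integers(50, 400))
        specs.append(SiteSpec(mid, f"t{i + 1:03d}", pos, mm, gu))
    return mirnas, tuple(specs)


def simulate_annotation(
    rng: np.random.Generator,
    background: list[str],
    n_terms: int = 40,
    size_range: tuple[int, int] = (10, 50),
    namespace: str = "BP",
) -> list[TermAnnotation]:
    """Random flat term annotation over a gene background."""
    bg = np.array(background)
    out = []
    for t in range(n_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(bg, size=min(size, len(bg)), replace=False)
        out.append(TermAnnotation(f"TERM:{t + 1:04d}", f"synthetic term {t + 1}",
                                  namespace, frozenset(members.tolist())))
    return out


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class Bundle:
    """Everything one end-to-end pipeline run needs, with ground truth."""

    config: SimConfig
    gene_counts: ExpressionMatrix
    gene_fpkm: ExpressionMatrix
    trait: pd.Series
    gene_truth: pd.DataFrame
    factors: pd.DataFrame
    mirna_counts: ExpressionMatrix
    mirna_truth: pd.DataFrame
    mirnas: dict[str, str]
    transcripts: dict[str, str]
    site_truth: pd.DataFrame
    degradome_tags: pd.DataFrame
    tf_annotation: dict[str, str]
    annotations: list[TermAnnotation]
    truth_edges: pd.DataFrame  # planted miRNA -> TF regulatory edges


def simulate_bundle(config: SimConfig) -> Bundle:
    """Generate a coherent synthetic study from one seeded stream.

    Stage order: gene expression, miRNA expression, miRNA sequences and
    planted target sites (targets are trait-module genes annotated as TFs,
    the targeting miRNAs are the planted differentially expressed ones),
    degradome tags, term annotation.
    """
    rng = np.random.default_rng(config.seed)
    expr = simulate_expression(config, rng)
    samples = config.sample_table()

    # miRNA expression: planted DE for the first n_de_mirnas
    mirna_ids = [f"mir{i + 1:03d}" for i in range(config.n_mirnas)]
    base = rng.uniform(4.0, 9.0, size=config.n_mirnas)
    # planted-DE miRNAs get moderately high baselines so the effect is not
    # drowned by shot noise at three replicates
    base[: config.n_de_mirnas] = rng.uniform(6.0, 9.0,
                                             size=config.n_de_mirnas)
    logtpm = base[:, None] + 0.2 * rng.standard_normal(
        (config.n_mirnas, config.n_samples))
    stage_b = config.stages[config.de_stage_pair[1]]
    b_cols = np.array([samples.loc[s, "stage"] == stage_b
                       for s in samples.index])
    de_mirna = np.zeros(config.n_mirnas, dtype=bool)
    de_mirna[: config.n_de_mirnas] = True
    logtpm[np.ix_(de_mirna, np.where(b_cols)[0])] += config.mirna_de_effect_log2fc
    mu = 2.0 ** logtpm
    r = 1.0 / config.nb_dispersion
    mcounts = rng.negative_binomial(r, r / (r + mu))
    mirna_counts = ExpressionMatrix(
        pd.DataFrame(mcounts, index=mirna_ids, columns=samples.index),
        samples, "count")
    mirna_truth = pd.DataFrame({"mirna": mirna_ids, "is_de": de_mirna})

    # planted sites: DE miRNAs target trait-module genes (annotated as TFs)
    trait_genes = list(
        expr.truth.loc[expr.truth["module"] == config.trait_module_index,
                       "gene"])
    n_sites = min(config.n_planted_sites, config.n_de_mirnas,
                  len(trait_genes))
    mirnas = {}
    specs = list(config.planted_site_spec or ())
    if not specs:
        for i in range(n_sites):
            mm, gu = COMPLIANT_PATTERNS[i % len(COMPLIANT_PATTERNS)]
            mid = mirna_ids[i]
            mirnas[mid] = _mirna_for_pattern(rng, config.mirna_length, mm, gu,
                                             None)
            pos = int(rng.integers(50, 400))
            specs.append(SiteSpec(mid, trait_genes[i], pos, mm, gu))
    for i, mid in enumerate(mirna_ids):
        if mid not in mirnas:
            mirnas[mid] = random_rna(rng, config.mirna_length)
    site_config = replace(config, planted_site_spec=tuple(specs))
    transcripts, site_truth = simulate_target_sites(site_config, mirnas, rng)
    degradome_tags = simulate_degradome(site_truth, transcripts, config, rng)

    # TF annotation: every planted target plus a few decoys
    tf_annotation = {
        spec.transcript_id: TF_FAMILIES[i % len(TF_FAMILIES)]
        for i, spec in enumerate(specs)
    }
    decoys = [g for g in expr.truth["gene"] if g not in tf_annotation][:5]
    for i, g in enumerate(decoys):
        tf_annotation[g] = TF_FAMILIES[(len(specs) + i) % len(TF_FAMILIES)]

    annotations = simulate_annotation(rng, list(expr.truth["gene"]))

    truth_edges = site_truth.loc[
        site_truth["compliant"]
        & site_truth["mirna_id"].isin(np.array(mirna_ids)[de_mirna])
        & site_truth["transcript_id"].isin(trait_genes),
        ["mirna_id", "transcript_id"],
    ].drop_duplicates().reset_index(drop=True)

    return Bundle(
        config=config,
        gene_counts=expr.counts,
        gene_fpkm=expr.fpkm,
        trait=expr.trait,
        gene_truth=expr.truth,
        factors=expr.factors,
        mirna_counts=mirna_counts,
        mirna_truth=mirna_truth,
        mirnas=mirnas,
        transcripts=transcripts,
        site_truth=site_truth,
        degradome_tags=degradome_tags,
        tf_annotation=tf_annotation,
        annotations=annotations,
        truth_edges=truth_edges,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> list[Path]:
    """Write the bundle in the pipeline's file formats (all plain text)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path):
        written.append(path)
        return path

    write_fasta(bundle.transcripts, _w(out / "transcripts.fasta"))
    write_fasta(bundle.mirnas, _w(out / "mirnas.fasta"))
    bundle.gene_counts.to_tsv(_w(out / "counts.tsv"))
    bundle.gene_fpkm.to_tsv(_w(out / "fpkm.tsv"))
    bundle.mirna_counts.to_tsv(_w(out / "mirna_counts.tsv"))
    bundle.gene_counts.samples.to_csv(_w(out / "samples.tsv"), sep="\t")
    bundle.trait.rename("bbr").to_frame().to_csv(_w(out / "trait.tsv"), sep="\t",
                                                 index_label="sample")
    bundle.degradome_tags.to_csv(_w(out / "degradome.tsv"), sep="\t", index=False)
    bundle.site_truth.to_csv(_w(out / "truth_sites.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "family": f} for g, f in sorted(bundle.tf_annotation.items())]
    ).to_csv(_w(out / "tf_annotation.tsv"), sep="\t", index=False)
    write_annotations(bundle.annotations, _w(out / "annotation.tsv"))
    return written
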