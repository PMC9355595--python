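"""Expression containers, TPM normalization and differential-expression screen.

The DE screen is a negative-binomial Wald test on library-size-normalized
counts with a method-of-moments dispersion per entity: log2 fold change is
computed on pseudocounted group means, its standard error by the delta method
under Var(X) = mu + alpha * mu^2, and the Wald statistic is referred to a
Student-t distribution with n_a + n_b - 2 degrees of freedom (the moment
dispersion estimate from three replicates per group is itself noisy, and the
t reference keeps the test close to nominal size there).  P-values are
adjusted by Benjamini-Hochberg.

Default screening thresholds follow common practice for this data type:
genes are called at |log2FC| > 1.5 with adjusted P < 0.05 (strict inequality
on the fold change), miRNAs at |log2FC| >= 1 with FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UNITS = ("count", "FPKM", "TPM")

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-4

# screening profiles: (lfc_threshold, strict inequality on |lfc|, alpha)
GENE_DE_PROFILE = dict(lfc_threshold=1.5, lfc_strict=True, alpha=0.05)
MIRNA_DE_PROFILE = dict(lfc_threshold=1.0, lfc_strict=False, alpha=0.05)


@dataclass
class ExpressionMatrix:
    """Entities x samples expression values with sample metadata.

    ``values`` is a DataFrame (rows = entities, columns = samples); ``samples``
    is indexed by sample id with columns ``stage`` and ``replicate``; ``units``
    is one of ``count``, ``FPKM``, ``TPM``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    units: str

    def __post_init__(self):
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}, got {self.units!r}")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def entities(self) -> pd.Index:
        return self.values.index

    def stage_of(self, sample: str) -> str:
        return self.samples.loc[sample, "stage"]

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.stage_of(s) == stage]

    def stage_means(self) -> pd.DataFrame:
        """Per-stage mean expression (entities x stages, stage order kept)."""
        stages = list(dict.fromkeys(self.samples.loc[self.values.columns, "stage"]))
        return pd.DataFrame(
            {st: self.values[self.samples_of_stage(st)].mean(axis=1) for st in stages}
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame, units: str) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="id"), samples, units)


def tpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize tag counts to transcripts-per-million: count/total * 1e6.

    No length correction is applied (appropriate for fixed-length small-RNA
    tags).  An all-zero column raises, naming the sample.
    """
    if counts.units != "count":
        raise ValueError("tpm_normalize expects a count matrix")
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {list(zero.index)}")
    tpm = counts.values / totals * 1e6
    return ExpressionMatrix(tpm, counts.samples, "TPM")


def size_factors(values: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, falling back to scaled column totals.

    The DESeq-style reference (geometric mean over samples) exists only for
    entities positive in every sample; when no such entity exists the column
    totals, scaled to geometric mean 1, are used instead.
    """
    arr = values.values.astype(float)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any():
        log_ref = np.log(arr[all_pos]).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(arr[all_pos]) - log_ref, axis=0))
    else:
        totals = arr.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=values.columns)


DE_COLUMNS = ["id", "log2fc", "p", "fdr", "is_de", "direction", "comparison"]


def de_screen(
    counts: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
    lfc_strict: bool = True,
    pseudocount: float = PSEUDOCOUNT,
    dispersion_floor: float = DISPERSION_FLOOR,
    prior_df: float = 4.0,
    comparison: str | None = None,
) -> pd.DataFrame:
    """Screen entities for differential expression between two sample groups.

    Fold change is b over a: ``log2((mean_b + c) / (mean_a + c))`` on
    normalized counts with pseudocount ``c``.  Per-entity moment dispersion
    estimates are shrunk toward the across-entity median with ``prior_df``
    pseudo-replicates (empirical-Bayes moderation in the spirit of limma /
    DESeq; ``prior_df = 0`` disables it), and the Wald statistic is referred
    to a Student t with ``n_a + n_b - 2 + prior_df`` degrees of freedom.  An
    entity is called DE when its |log2FC| exceeds ``lfc_threshold`` (strictly
    if ``lfc_strict``) and its BH-adjusted p-value is below ``alpha``.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if counts.units != "count":
        raise ValueError("de_screen expects a count matrix")

    sf = size_factors(counts.values[group_a + group_b])
    norm = counts.values[group_a + group_b] / sf

    xa = norm[group_a].values
    xb = norm[group_b].values
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)

    # method-of-moments NB dispersion, averaged over groups with signal,
    # then moderated toward the across-entity median
    with np.errstate(divide="ignore", invalid="ignore"):
        aa = np.where(ma > 0, (va - ma) / ma**2, np.nan)
        ab = np.where(mb > 0, (vb - mb) / mb**2, np.nan)
    raw = np.fmax(np.nan_to_num(np.nanmean(np.stack([aa, ab]), axis=0),
                                nan=0.0), 0.0)
    df_resid = na + nb - 2
    if prior_df > 0 and len(raw):
        common = float(np.median(raw))
        raw = (prior_df * common + df_resid * raw) / (prior_df + df_resid)
    disp = np.fmax(raw, dispersion_floor)

    c = pseudocount
    log2fc = np.log2((mb + c) / (ma + c))
    # delta method: Var(log mean) ~ (1/n) (1/mu + alpha) under Var = mu+alpha mu^2
    var_log = (1.0 / na) * (1.0 / (ma + c) + disp) + (1.0 / nb) * (
        1.0 / (mb + c) + disp
    )
    se = np.sqrt(var_log) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2 * stats.t.sf(np.abs(wald), df=df_resid + prior_df)
    fdr = multipletests(p, method="fdr_bh")[1]

    exceeds = np.abs(log2fc) > lfc_threshold if lfc_strict else np.abs(
        log2fc) >= lfc_threshold
    is_de = exceeds & (fdr < alpha)
    out = pd.DataFrame(
        {
            "id": counts.entities,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "is_de": is_de,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "comparison": comparison or "b_vs_a",
        }
    ).reset_index(drop=True)
    return out[DE_COLUMNS]
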