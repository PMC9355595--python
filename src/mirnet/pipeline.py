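"""End-to-end orchestration of the analysis stages with a run manifest.

Each stage reads and writes the module file interfaces into its own
subdirectory of the output tree, so no stage mutates another stage's inputs.
The manifest records the configuration hash, seed, executed stages and a
SHA-256 checksum of every file written; deterministic stages reproduce
identical checksums under an identical configuration and seed.

The shipped default profile ("pmume2022") collects every screening threshold
in one place: gene DE at |log2FC| > 1.5 / adjusted P < 0.05; miRNA DE at
|log2FC| >= 1 / FDR < 0.05; soft powers 9 (genes) and 8 (miRNAs); minimum
module size 50; merge threshold 0.8; expression filters >= 2 across 70% of
samples with SD > 0.25; degradome keep categories <= 2; MFE ratio >= 74%.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpr import NetworkParams, coexpression_pipeline
from .degradome import build_profiles, validate_targets
from .enrich import enrich, read_annotations
from .netbuild import assemble, mirna_tf_pairs
from .quant import (GENE_DE_PROFILE, MIRNA_DE_PROFILE, ExpressionMatrix,
                    de_screen, tpm_normalize)
from .sequtil import read_fasta
from .synthio import SimConfig, simulate_bundle, write_bundle
from .targetscan import predict_targets

log = logging.getLogger("mirnet")

#: the paper-default threshold profile; one place to audit every number
PROFILE_PMUME2022 = {
    "gene_de": dict(GENE_DE_PROFILE),
    "mirna_de": dict(MIRNA_DE_PROFILE),
    "gene_power": 9,
    "mirna_power": 8,
    "min_module_size": 50,
    "merge_similarity": 0.8,
    "expr_min_value": 2.0,
    "expr_min_fraction": 0.7,
    "expr_min_sd": 0.25,
    "keep_category": 2,
    "mfe_threshold": 74.0,
    "max_gaps": 1,
    "k_neighbors": 10,
    "enrich_alpha": 0.05,
}

STAGES = ["simulate", "quantify", "de", "predict-targets",
          "degradome-validate", "coexpr", "enrich", "network"]


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable)."""

    seed: int = 0
    outdir: str = "mirnet_out"
    sim: dict = field(default_factory=dict)
    profile: dict = field(default_factory=lambda: dict(PROFILE_PMUME2022))
    min_module_size: int | None = None  # convenience override for small runs

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  outdir: str | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {"seed", "outdir", "sim", "profile",
                              "min_module_size"}
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        profile = dict(PROFILE_PMUME2022)
        profile.update(raw.get("profile") or {})
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "mirnet_out")),
            sim=dict(raw.get("sim") or {}),
            profile=profile,
            min_module_size=raw.get("min_module_size"),
        )
        if seed is not None:
            cfg.seed = seed
        if outdir is not None:
            cfg.outdir = outdir
        cfg.validate()
        return cfg

    def validate(self) -> None:
        p = self.profile
        for key in ("gene_power", "mirna_power"):
            if int(p[key]) < 1:
                raise ConfigError(f"profile.{key} must be a positive integer")
        if not 0 < p["merge_similarity"] < 1:
            raise ConfigError("profile.merge_similarity must be in (0, 1)")
        if p["keep_category"] not in (0, 1, 2, 3, 4):
            raise ConfigError("profile.keep_category must be in 0..4")
        try:
            self.sim_config()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid sim section: {exc}") from exc

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def network_params(self, kind: str) -> NetworkParams:
        p = self.profile
        return NetworkParams(
            soft_power=p["gene_power"] if kind == "gene" else p["mirna_power"],
            min_module_size=(self.min_module_size
                             or p["min_module_size"]),
            merge_similarity=p["merge_similarity"],
            min_value=p["expr_min_value"],
            min_fraction=p["expr_min_fraction"],
            min_sd=p["expr_min_sd"],
        )


class ConfigError(ValueError):
    """Raised when the run configuration fails validation."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    checksums: dict[str, str]
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


class PipelineRun:
    """Stateful pipeline: stage methods consume earlier stage outputs."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []
        self.executed: list[str] = []
        self.bundle = None
        self.results: dict = {}

    # -- helpers ---------------------------------------------------------

    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _write_df(self, df: pd.DataFrame, path: Path, **kw) -> None:
        df.to_csv(path, sep="\t", index=False, **kw)
        self.written.append(path)

    # -- stages ----------------------------------------------------------

    def simulate(self) -> None:
        log.info("simulate: seed=%d", self.config.seed)
        self.bundle = simulate_bundle(self.config.sim_config())
        files = write_bundle(self.bundle, self._stage_dir("simulate"))
        self.written.extend(files)
        self.executed.append("simulate")

    def quantify(self) -> None:
        b = self._require_bundle()
        tpm = tpm_normalize(b.mirna_counts)
        tpm.to_tsv(self._stage_dir("quantify") / "mirna_tpm.tsv")
        self.written.append(self._stage_dir("quantify") / "mirna_tpm.tsv")
        self.results["mirna_tpm"] = tpm
        self.executed.append("quantify")

    def de(self) -> None:
        b = self._require_bundle()
        prof = self.config.profile
        cfg = b.config
        stage_a = cfg.stages[cfg.de_stage_pair[0]]
        stage_b = cfg.stages[cfg.de_stage_pair[1]]
        ga = b.gene_counts.samples_of_stage(stage_a)
        gb = b.gene_counts.samples_of_stage(stage_b)
        comparison = f"{stage_a}_vs_{stage_b}"
        log.info("de: %s, gene thresholds %s, miRNA thresholds %s",
                 comparison, prof["gene_de"], prof["mirna_de"])
        gene_de = de_screen(b.gene_counts, ga, gb, comparison=comparison,
                            **prof["gene_de"])
        mirna_de = de_screen(b.mirna_counts, ga, gb, comparison=comparison,
                             **prof["mirna_de"])
        d = self._stage_dir("de")
        self._write_df(gene_de, d / "gene_de.tsv")
        self._write_df(mirna_de, d / "mirna_de.tsv")
        self.results["gene_de"] = gene_de
        self.results["mirna_de"] = mirna_de
        self.executed.append("de")

    def predict_targets(self) -> None:
        b = self._require_bundle()
        preds = predict_targets(b.mirnas, b.transcripts,
                                max_gaps=self.config.profile["max_gaps"])
        self._write_df(preds, self._stage_dir("predict-targets") / "predictions.tsv")
        self.results["predictions"] = preds
        self.executed.append("predict-targets")

    def degradome_validate(self) -> None:
        b = self._require_bundle()
        preds = self.results["predictions"]
        lengths = {tid: len(seq) for tid, seq in b.transcripts.items()}
        profiles = build_profiles(b.degradome_tags, lengths)
        calls = validate_targets(preds, profiles,
                                 keep_category=self.config.profile["keep_category"])
        self._write_df(calls, self._stage_dir("degradome-validate") / "calls.tsv")
        self.results["calls"] = calls
        self.executed.append("degradome-validate")

    def coexpr(self) -> None:
        b = self._require_bundle()
        params = self.config.network_params("gene")
        log.info("coexpr: power=%d min_module_size=%d merge=%.2f",
                 params.soft_power, params.min_module_size,
                 params.merge_similarity)
        modules, trait_table = coexpression_pipeline(b.gene_fpkm, params,
                                                     b.trait)
        d = self._stage_dir("coexpr")
        member_rows = [
            {"entity": g, "module": m.label,
             "kme": (float(m.kme[g]) if m.kme is not None else np.nan)}
            for m in modules for g in m.members
        ]
        self._write_df(pd.DataFrame(member_rows,
                                    columns=["entity", "module", "kme"]),
                       d / "modules.tsv")
        self._write_df(trait_table, d / "trait_assoc.tsv")
        eig = pd.DataFrame({m.label: m.eigengene for m in modules
                            if m.eigengene is not None})
        eig.to_csv(d / "eigengenes.tsv", sep="\t", index_label="sample")
        self.written.append(d / "eigengenes.tsv")
        self.results["modules"] = modules
        self.results["trait_table"] = trait_table
        self.executed.append("coexpr")

    def enrich(self) -> None:
        b = self._require_bundle()
        gene_de = self.results["gene_de"]
        candidates = set(gene_de.loc[gene_de["is_de"], "id"])
        background = set(b.gene_truth["gene"])
        table = enrich(candidates & background, b.annotations,
                       background=background,
                       alpha=self.config.profile["enrich_alpha"])
        self._write_df(table, self._stage_dir("enrich") / "enrichment.tsv")
        self.results["enrichment"] = table
        self.executed.append("enrich")

    def network(self) -> None:
        b = self._require_bundle()
        mirna_de = self.results["mirna_de"]
        demirs = set(mirna_de.loc[mirna_de["is_de"], "id"])
        modules = self.results["modules"]
        trait_table = self.results["trait_table"]
        # trait-associated modules: significant trait correlation
        assoc = set(trait_table.loc[trait_table["p"] < 0.05, "module"])
        trait_modules = [m for m in modules if m.label in assoc]
        edges = mirna_tf_pairs(self.results["calls"], b.tf_annotation, demirs)
        de_status = {g: "DE" for g in
                     self.results["gene_de"].loc[
                         self.results["gene_de"]["is_de"], "id"]}
        de_status.update({m: "DEmiR" for m in demirs})
        net = assemble(trait_modules, edges, b.gene_fpkm,
                       k_neighbors=self.config.profile["k_neighbors"],
                       de_status=de_status)
        d = self._stage_dir("network")
        net.write_sif(d / "network.sif")
        net.write_graphml(d / "network.graphml")
        net.write_tables(d / "nodes.tsv", d / "edges.tsv")
        self.written.extend([d / "network.sif", d / "network.graphml",
                             d / "nodes.tsv", d / "edges.tsv"])
        self.results["network"] = net
        self.executed.append("network")

    # -- driver ----------------------------------------------------------

    def _require_bundle(self):
        if self.bundle is None:
            raise RuntimeError("run the simulate stage first")
        return self.bundle

    def run(self, stages: list[str]) -> RunManifest:
        stage_fn = {
            "simulate": self.simulate,
            "quantify": self.quantify,
            "de": self.de,
            "predict-targets": self.predict_targets,
            "degradome-validate": self.degradome_validate,
            "coexpr": self.coexpr,
            "enrich": self.enrich,
            "network": self.network,
        }
        for s in stages:
            if s not in stage_fn:
                raise ConfigError(f"unknown stage: {s}")
            stage_fn[s]()
        manifest = RunManifest(
            config_hash=hashlib.sha256(
                json.dumps({"seed": self.config.seed, "sim": self.config.sim,
                            "profile": self.config.profile},
                           sort_keys=True).encode()).hexdigest(),
            seed=self.config.seed,
            stages=list(self.executed),
            checksums={str(p.relative_to(self.outdir)): _sha256(p)
                       for p in sorted(set(self.written))},
        )
        manifest.write(self.outdir / "manifest.json")
        return manifest


def run_all(config: RunConfig) -> tuple[PipelineRun, RunManifest]:
    """Run every stage in order on a synthetic bundle."""
    run = PipelineRun(config)
    manifest = run.run(STAGES)
    return run, manifest
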