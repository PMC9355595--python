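"""The synthetic-data generator: determinism, planted structure, truth labels."""

import numpy as np
import pandas as pd
import pytest

from mirnet.degradome import build_profile
from mirnet.sequtil import revcomp_rna
from mirnet.synthio import (SimConfig, SiteSpec, planted_site_benchmark,
                            simulate_bundle, simulate_degradome,
                            simulate_expression, simulate_target_sites,
                            site_compliance)
from mirnet.targetscan import align_duplex, apply_criteria


class TestSimConfig:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(trait_module_index=5, n_modules=3)
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=0.0)


class TestSimulateExpression:
    def test_same_seed_reproduces_identical_output(self):
        cfg = SimConfig(seed=11)
        a = simulate_expression(cfg)
        b = simulate_expression(cfg)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.fpkm.values, b.fpkm.values)
        pd.testing.assert_series_equal(a.trait, b.trait)

    def test_zero_correlation_gives_independent_genes(self):
        cfg = SimConfig(seed=3, within_module_cor=0.0, n_de_genes=0)
        sim = simulate_expression(cfg)
        lf = np.log2(sim.fpkm.values.values + 1)
        r = np.corrcoef(lf[:200])
        off = np.abs(r[np.triu_indices(200, 1)])
        assert off.mean() < 0.3  # |r| of null pairs at 12 samples

    def test_planted_within_module_correlation(self):
        cfg = SimConfig(seed=1, n_modules=3, within_module_cor=0.8,
                        n_genes=600)
        sim = simulate_expression(cfg)
        lf = np.log2(sim.fpkm.values.values + 1)
        m0 = sim.truth.index[sim.truth["module"] == 0]
        r = np.corrcoef(lf[m0])
        mean_r = np.abs(r[np.triu_indices(len(m0), 1)]).mean()
        assert 0.7 <= mean_r <= 0.9

    def test_planted_de_effect_realized(self):
        cfg = SimConfig(seed=5, nb_dispersion=0.05)
        sim = simulate_expression(cfg)
        de = sim.truth.loc[sim.truth["is_de"], "gene"]
        stages = sim.counts.samples["stage"]
        a_cols = stages[stages == "EndodorI"].index
        b_cols = stages[stages == "EndodorII"].index
        fpkm = sim.fpkm.values
        lfc = np.log2(fpkm.loc[de, b_cols].mean(axis=1)
                      / fpkm.loc[de, a_cols].mean(axis=1))
        assert abs(lfc.mean() - cfg.de_effect_log2fc) < 0.3

    def test_trait_tracks_trait_module_factor(self):
        sim = simulate_expression(SimConfig(seed=9))
        r = np.corrcoef(sim.trait.values, sim.factors["M0"].values)[0, 1]
        assert abs(r) >= 0.9


class TestSiteCompliance:
    def test_empty_pattern_is_compliant(self):
        v = site_compliance("ACGUACGUACGUACGUACGUA", (), ())
        assert v["compliant"] and v["score"] == 0

    def test_mismatch_at_position_10_fails_criterion_5(self):
        v = site_compliance("ACGUACGUACGUACGUACGUA", (10,), ())
        assert not v["c5"] and not v["compliant"]
        assert v["c2"] and v["c6"]

    def test_hand_counted_weighted_mismatches(self):
        # mismatches at {1, 19, 20, 21} plus one wobble: score 4.5 > 4
        v = site_compliance("GCGUACGUACGUACGUACGUA", (1, 19, 20, 21), (3,))
        assert v["score"] == 4.5
        assert not v["c2"] and not v["compliant"]

    def test_pattern_position_outside_mirna_rejected(self):
        with pytest.raises(ValueError, match="22"):
            site_compliance("ACGUACGUACGUACGUACGUA", (22,), ())


class TestSimulateTargetSites:
    def mirnas(self):
        return {"mir1": "UGCCUGGCUCCCUGUAUGCCA"}

    def test_perfect_site_embeds_reverse_complement(self):
        spec = SiteSpec("mir1", "tx1", 101)
        cfg = SimConfig(seed=2, planted_site_spec=(spec,))
        tx, truth = simulate_target_sites(cfg, self.mirnas())
        m = self.mirnas()["mir1"]
        assert tx["tx1"][100:121] == revcomp_rna(m)
        assert truth.iloc[0]["compliant"]
        assert truth.iloc[0]["cleavage_pos"] == 101 + 21 - 10

    def test_truth_flags_equal_scanner_verdict(self, rng):
        mirnas, specs = planted_site_benchmark(rng, n_compliant=12,
                                               n_violators=12)
        cfg = SimConfig(seed=4, planted_site_spec=specs)
        tx, truth = simulate_target_sites(cfg, mirnas)
        for row in truth.itertuples(index=False):
            window = tx[row.transcript_id][row.start - 1 : row.end]
            d = align_duplex(mirnas[row.mirna_id], window)
            v = apply_criteria(d)
            assert v.as_tuple() == (row.c1, row.c2, row.c3, row.c4, row.c5,
                                    row.c6), row.mirna_id
            assert d.score == row.score

    def test_gu_impossible_at_a_or_c_base_rejected(self):
        spec = SiteSpec("mir1", "tx1", 50, gu_positions=(2,))  # base G? no: C
        cfg = SimConfig(seed=2, planted_site_spec=(spec,))
        mirnas = {"mir1": "ACGUACGUACGUACGUACGUA"}  # position 2 = C
        with pytest.raises(ValueError, match="wobble"):
            simulate_target_sites(cfg, mirnas)

    def test_benchmark_violators_fail_exactly_one_criterion(self, rng):
        mirnas, specs = planted_site_benchmark(rng, n_compliant=6,
                                               n_violators=18)
        crits = ("c1", "c2", "c3", "c4", "c5", "c6")
        seen = set()
        for spec in specs[6:]:
            v = site_compliance(mirnas[spec.mirna_id],
                                spec.mismatch_positions, spec.gu_positions)
            failed = [c for c in crits if not v[c]]
            assert len(failed) == 1
            seen.add(failed[0])
        assert seen == set(crits)


class TestSimulateDegradome:
    def setup_sites(self, rng, peak=50, noise=0.0):
        mirnas, specs = planted_site_benchmark(rng, n_compliant=1,
                                               n_violators=0)
        cfg = SimConfig(seed=6, planted_site_spec=specs,
                        degradome_peak_height=peak,
                        degradome_noise_rate=noise)
        tx, truth = simulate_target_sites(cfg, mirnas)
        tags = simulate_degradome(truth, tx, cfg)
        return tx, truth, tags

    def test_zero_noise_single_peak_is_only_nonzero_position(self, rng):
        tx, truth, tags = self.setup_sites(rng)
        assert len(tags) == 1
        assert tags.iloc[0]["position"] == truth.iloc[0]["cleavage_pos"]
        assert tags.iloc[0]["count"] == 50

    def test_peak_dominates_low_noise_background(self, rng):
        tx, truth, tags = self.setup_sites(rng, peak=50, noise=0.05)
        tid = truth.iloc[0]["transcript_id"]
        profile = build_profile(tags, tid, len(tx[tid]))
        assert profile.at(int(truth.iloc[0]["cleavage_pos"])) >= 50
        assert (profile.counts == profile.counts.max()).sum() == 1

    def test_single_read_site_construction(self, rng):
        tx, truth, tags = self.setup_sites(rng, peak=1)
        assert tags.iloc[0]["count"] == 1

    def test_profile_totals_match_generator_output(self, rng):
        tx, truth, tags = self.setup_sites(rng, peak=30, noise=0.1)
        for tid, seq in tx.items():
            profile = build_profile(tags, tid, len(seq))
            assert profile.total == tags.loc[
                tags["transcript_id"] == tid, "count"].sum()


class TestBundle:
    def test_bundle_is_deterministic_and_coherent(self, tmp_path):
        cfg = SimConfig(seed=21)
        b1 = simulate_bundle(cfg)
        b2 = simulate_bundle(cfg)
        pd.testing.assert_frame_equal(b1.gene_counts.values,
                                      b2.gene_counts.values)
        assert b1.mirnas == b2.mirnas
        assert b1.transcripts == b2.transcripts
        pd.testing.assert_frame_equal(b1.degradome_tags, b2.degradome_tags)
        # planted regulatory edges target TF-annotated trait-module genes
        trait_genes = set(b1.gene_truth.loc[
            b1.gene_truth["module"] == cfg.trait_module_index, "gene"])
        for e in b1.truth_edges.itertuples(index=False):
            assert e.transcript_id in trait_genes
            assert e.transcript_id in b1.tf_annotation
            assert b1.mirna_truth.set_index("mirna").loc[e.mirna_id, "is_de"]

    def test_write_bundle_round_trips_fasta(self, tmp_path):
        from mirnet.sequtil import read_fasta
        from mirnet.synthio import write_bundle
        b = simulate_bundle(SimConfig(seed=22))
        write_bundle(b, tmp_path)
        assert read_fasta(tmp_path / "mirnas.fasta") == b.mirnas
        assert read_fasta(tmp_path / "transcripts.fasta") == b.transcripts
        assert (tmp_path / "truth_sites.tsv").exists()
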