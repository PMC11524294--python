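"""Unit and property tests for the synthetic-data generator."""

import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

from nucredit import io as nio
from nucredit.enrichment import endosymbiont_fisher
from nucredit.simulate import (
    SimConfig,
    assign_roles,
    embed_motif_context,
    generate_transcripts,
    plant_sites,
    simulate_all,
    simulate_annotations,
    simulate_expression,
    simulate_pileup,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestGenerateTranscripts:
    def test_regions_partition_and_cds_structure(self, tiny_config):
        transcripts = generate_transcripts(tiny_config)
        assert len(transcripts) == tiny_config.n_transcripts
        for t in transcripts.values():
            assert t.utr5[0] == 0 and t.utr3[1] == len(t)
            cds = t.cds_sequence
            assert cds.startswith("ATG")
            assert len(cds) % 3 == 0
            internal = [cds[k : k + 3] for k in range(0, len(cds) - 3, 3)]
            assert not any(c in STOPS for c in internal)

    def test_pure_cds_when_utrs_empty(self):
        cfg = SimConfig(n_transcripts=3, utr5_len=(0, 0), utr3_len=(0, 0), seed=1)
        for t in generate_transcripts(cfg).values():
            assert t.utr5 == (0, 0)
            assert t.cds == (0, len(t))

    def test_fixed_cds_length(self):
        cfg = SimConfig(n_transcripts=5, cds_len=(300, 300), seed=2)
        for t in generate_transcripts(cfg).values():
            assert t.cds[1] - t.cds[0] == 300

    def test_same_seed_identical_fasta(self, tmp_path, tiny_config):
        for d in ("a", "b"):
            nio.write_transcripts(
                generate_transcripts(tiny_config).values(),
                tmp_path / f"{d}.fasta",
                tmp_path / f"{d}.gff3",
            )
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


class TestPlantSites:
    def test_point_mass_weights_give_c_to_u_only(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, editing_types={"C-to-U": 1.0})
        sites = plant_sites(generate_transcripts(cfg), cfg)
        assert len(sites) == cfg.n_sites
        assert all((s.ref_base, s.alt_base) == ("C", "T") for s in sites)

    def test_degenerate_degree_range(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, degree_range=(0.42, 0.42))
        sites = plant_sites(generate_transcripts(cfg), cfg)
        assert all(s.true_degree == pytest.approx(0.42) for s in sites)

    def test_coordinates_unique_and_match_reference(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_sites=100)
        transcripts = generate_transcripts(cfg)
        sites = plant_sites(transcripts, cfg)
        coords = {(s.transcript_id, s.position) for s in sites}
        assert len(coords) == 100
        for s in sites:
            assert transcripts[s.transcript_id].sequence[s.position] == s.ref_base

    def test_too_many_sites_raises(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_sites=10**6)
        with pytest.raises(ValueError, match="exceeds"):
            plant_sites(generate_transcripts(cfg), cfg)


class TestSimulatePileup:
    def test_noise_free_limit_all_reference(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, error_rate=0.0)
        transcripts = generate_transcripts(cfg)
        for col in simulate_pileup(transcripts, [], cfg):
            assert col.counts[col.ref] == col.coverage

    def test_full_degree_zero_error_alt_equals_coverage(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, error_rate=0.0, degree_range=(1.0, 1.0),
            editing_types={"C-to-U": 1.0}, n_sites=10,
        )
        transcripts = generate_transcripts(cfg)
        sites = plant_sites(transcripts, cfg)
        planted = {(s.transcript_id, s.position) for s in sites}
        for col in simulate_pileup(transcripts, sites, cfg):
            if (col.transcript_id, col.position) in planted:
                assert col.counts["T"] == col.coverage

    def test_counts_sum_to_coverage(self, tiny_config):
        transcripts = generate_transcripts(tiny_config)
        sites = plant_sites(transcripts, tiny_config)
        for col in simulate_pileup(transcripts, sites, tiny_config):
            assert sum(col.counts.values()) == col.coverage

    def test_half_degree_alt_fraction_concentrates(self):
        # Binomial(1000, ~0.5): P(|X/n - 0.5| > 0.05) < 1%, so over 150 sites
        # at least 99% should land inside +/-0.05 with large margin.
        cfg = SimConfig(
            n_transcripts=15, n_sites=150, degree_range=(0.5, 0.5),
            coverage_mean=1000.0, error_rate=0.0,
            editing_types={"C-to-U": 1.0}, seed=3,
        )
        transcripts = generate_transcripts(cfg)
        sites = plant_sites(transcripts, cfg)
        planted = {(s.transcript_id, s.position) for s in sites}
        fractions = [
            col.counts["T"] / col.coverage
            for col in simulate_pileup(transcripts, sites, cfg)
            if (col.transcript_id, col.position) in planted
        ]
        assert len(fractions) == 150
        inside = np.mean([abs(f - 0.5) <= 0.05 for f in fractions])
        assert inside >= 0.99


class TestSimulateExpression:
    @staticmethod
    def _roles(cfg, n_targets=4):
        transcripts = generate_transcripts(cfg)
        sites = plant_sites(transcripts, cfg)
        return assign_roles(transcripts, sites, cfg)

    def test_perfect_rho_identical_rank_orders(self):
        cfg = SimConfig(
            n_transcripts=20, n_sites=60, editing_types={"C-to-U": 1.0},
            n_clusters=1, targets_per_cluster=4, ppr_per_cluster=1,
            within_cluster_rho=1.0, n_samples=12, seed=4,
        )
        expr = simulate_expression(self._roles(cfg), cfg)
        ranks = expr.rank(axis=1)
        first = ranks.iloc[0]
        for i in range(1, len(ranks)):
            assert (ranks.iloc[i] == first).all()

    def test_between_cluster_rho_near_zero(self):
        cfg = SimConfig(
            n_transcripts=30, n_sites=100, editing_types={"C-to-U": 1.0},
            n_clusters=2, targets_per_cluster=4, ppr_per_cluster=1,
            within_cluster_rho=0.9, n_samples=1000, seed=5,
        )
        roles = self._roles(cfg)
        expr = simulate_expression(roles, cfg)
        rho = stats.spearmanr(expr.to_numpy().T)[0]
        c1 = np.flatnonzero(roles["cluster"].to_numpy() == 1)
        c2 = np.flatnonzero(roles["cluster"].to_numpy() == 2)
        between = [abs(rho[i, j]) for i, j in itertools.product(c1, c2)]
        # null Spearman rho has var ~ 1/(n-1) => sd ~ 0.032 at n=1000
        assert np.median(between) < 0.1

    def test_within_cluster_pairs_reach_target(self):
        cfg = SimConfig(
            n_transcripts=30, n_sites=100, editing_types={"C-to-U": 1.0},
            n_clusters=1, targets_per_cluster=4, ppr_per_cluster=1,
            within_cluster_rho=0.9, n_samples=200, seed=6,
        )
        expr = simulate_expression(self._roles(cfg), cfg)
        rho = stats.spearmanr(expr.to_numpy().T)[0]
        n = len(expr)
        pairs = [rho[i, j] for i in range(n) for j in range(i + 1, n)]
        assert len(pairs) == 10
        assert all(r > 0.7 for r in pairs)
        assert np.mean(pairs) == pytest.approx(0.9, abs=0.08)

    def test_too_few_samples_refused(self):
        cfg = SimConfig(n_samples=4)
        with pytest.raises(ValueError, match="samples"):
            simulate_expression(None, cfg)


class TestEmbedMotifContext:
    @staticmethod
    def _ctu_setup(motif_prob, seed=7, n_sites=120):
        cfg = SimConfig(
            n_transcripts=20, n_sites=n_sites, editing_types={"C-to-U": 1.0},
            motif_prob=motif_prob, seed=seed,
        )
        transcripts = generate_transcripts(cfg)
        sites = plant_sites(transcripts, cfg)
        return cfg, transcripts, sites

    def test_certain_motif_all_flanks_purine(self):
        cfg, transcripts, sites = self._ctu_setup(1.0)
        planted_pos = {(s.transcript_id, s.position) for s in sites}
        rewritten = embed_motif_context(transcripts, sites, cfg)
        skipped_neighbours = 0
        for s in sites:
            seq = rewritten[s.transcript_id].sequence
            assert seq[s.position] == "C"
            for p in (s.position - 1, s.position + 1):
                if (s.transcript_id, p) in planted_pos:
                    skipped_neighbours += 1  # never rewrites another site's base
                    continue
                assert seq[p] in "AG"
        assert skipped_neighbours < len(sites)

    def test_zero_motif_prob_leaves_sequences_unchanged(self):
        cfg, transcripts, sites = self._ctu_setup(0.0)
        rewritten = embed_motif_context(transcripts, sites, cfg)
        for tid in transcripts:
            assert rewritten[tid].sequence == transcripts[tid].sequence

    def test_no_internal_stop_created(self):
        cfg, transcripts, sites = self._ctu_setup(1.0, seed=8, n_sites=200)
        rewritten = embed_motif_context(transcripts, sites, cfg)
        for t in rewritten.values():
            cds = t.cds_sequence
            internal = [cds[k : k + 3] for k in range(0, len(cds) - 3, 3)]
            assert not any(c in STOPS for c in internal)

    def test_partial_motif_prob_purine_fraction_in_band(self):
        # 0.8 of 500 sites rewritten to purines, the rest keep the background
        # composition (~50% purine): expected fraction ~0.9, binomial CI wide
        cfg, transcripts, sites = self._ctu_setup(0.8, seed=9, n_sites=500)
        rewritten = embed_motif_context(transcripts, sites, cfg)
        planted_pos = {(s.transcript_id, s.position) for s in sites}
        upstream = [
            rewritten[s.transcript_id].sequence[s.position - 1] in "AG"
            for s in sites
            if (s.transcript_id, s.position - 1) not in planted_pos
        ]
        frac = np.mean(upstream)
        assert 0.8 <= frac <= 0.95


class TestSimulateAnnotations:
    def test_null_fisher_type_one_error_controlled(self):
        cfg = SimConfig(
            edited_fraction_endo=0.2, edited_fraction_other=0.2, seed=10
        )
        genes = [f"G{i}" for i in range(400)]
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            c = dataclasses.replace(cfg, seed=1000 + rep)
            labels = simulate_annotations(genes, c)
            if labels["endosymbiont"].nunique() < 2:
                continue
            res = endosymbiont_fisher(labels)
            rejections += res["p_value"] < 0.05
        # one-sided exact test is conservative under the null
        assert rejections / n_reps <= 0.09

    def test_planted_stratum_difference_detected(self):
        cfg = SimConfig(endo_fraction=7036 / 42036, seed=12)
        genes = [f"G{i}" for i in range(42036)]
        labels = simulate_annotations(genes, cfg)
        res = endosymbiont_fisher(labels)
        assert res["endo_edited_fraction"] == pytest.approx(0.273, abs=0.02)
        assert res["p_value"] < 1e-10

    def test_ground_truth_override(self):
        cfg = SimConfig(seed=13)
        genes = ["a", "b", "c"]
        labels = simulate_annotations(genes, cfg, edited={"a": True})
        assert labels["edited"].tolist() == [1, 0, 0]


class TestDeterminismAndRoundTrip:
    def test_same_seed_byte_identical_outputs(self, tmp_path, tiny_config):
        p1 = simulate_all(tiny_config, tmp_path / "r1")
        p2 = simulate_all(tiny_config, tmp_path / "r2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_truth_table_round_trip(self, tmp_path, tiny_config):
        transcripts = generate_transcripts(tiny_config)
        sites = plant_sites(transcripts, tiny_config)
        nio.write_truth(sites, tmp_path / "truth.tsv")
        assert nio.read_truth(tmp_path / "truth.tsv") == sites
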