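import dataclasses

import numpy as np
import pytest

from intronprom.est import build_msa, call_consensus, match_consensus, to_transcript_orientation
from intronprom.inr import default_inr_pwm, scan_inr
from intronprom.synth import (
    PlantedPromoter,
    SynthConfig,
    SynthDataset,
    config_from_yaml,
    config_to_yaml,
    generate_dataset,
    generate_genome,
    simulate_cage,
    simulate_ests,
    simulate_hotspots,
    write_dataset,
)


def small_config(**kw):
    base = dict(
        seed=3,
        genome_length=6000,
        planted_promoters=(PlantedPromoter(1200, "+", 3),),
        n_cell_types_dnase=12,
        n_cell_types_h3k4me3=6,
        cage_cell_types=5,
        lnc_length=400,
        n_ests=6,
        est_length_mean=250.0,
        est_length_sd=40.0,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestGenerateGenome:
    def test_zero_gc_only_at_outside_planted_motifs(self):
        cfg = small_config(gc_fraction=0.0)
        genome, truth = generate_genome(cfg)
        pwm = default_inr_pwm()
        planted = set()
        for center, strand in truth.inr_centers:
            off = pwm.plus_one_offset if strand == "+" else pwm.width - 1 - pwm.plus_one_offset
            planted.update(range(center - off, center - off + pwm.width))
        outside = {genome[i] for i in range(len(genome)) if i not in planted}
        assert outside <= {"A", "T"}

    def test_planted_centers_recovered_at_high_cutoff(self):
        cfg = small_config()
        genome, truth = generate_genome(cfg)
        hits = {(h.center, h.strand) for h in scan_inr(genome, default_inr_pwm(), 0.99)}
        assert set(truth.inr_centers) <= hits

    def test_minus_strand_promoter_planted_on_minus(self):
        cfg = small_config(planted_promoters=(PlantedPromoter(2000, "-", 2),))
        genome, truth = generate_genome(cfg)
        hits = {(h.center, h.strand) for h in scan_inr(genome, default_inr_pwm(), 0.99)}
        assert set(truth.inr_centers) <= hits
        assert all(s == "-" for _, s in truth.inr_centers)

    def test_same_seed_identical_output(self):
        g1, _ = generate_genome(small_config())
        g2, _ = generate_genome(small_config())
        assert g1 == g2

    def test_different_seed_different_output(self):
        g1, _ = generate_genome(small_config(seed=1))
        g2, _ = generate_genome(small_config(seed=2))
        assert g1 != g2

    def test_motif_outside_genome_rejected(self):
        cfg = small_config(planted_promoters=(PlantedPromoter(5995, "+", 2),))
        with pytest.raises(ValueError):
            generate_genome(cfg)


class TestSimulateHotspots:
    def test_no_background_full_presence_one_hotspot_per_promoter(self):
        cfg = small_config(background_hotspot_rate=0.0, promoter_presence_prob=1.0)
        tracks = simulate_hotspots(cfg)
        for by_ct in tracks.values():
            for records in by_ct.values():
                assert len(records) == len(cfg.planted_promoters)

    def test_zero_presence_prob_gives_pure_background(self):
        cfg = small_config(promoter_presence_prob=0.0, background_hotspot_rate=0.0)
        tracks = simulate_hotspots(cfg)
        assert all(not recs for by in tracks.values() for recs in by.values())

    def test_promoter_module_prevalence_is_binomial(self):
        # mean prevalence at the promoter across seeds ~ Binomial(n, p)/1,
        # so the mean over k seeds sits within 3 * sd/sqrt(k) of n*p
        n, p, k = 40, 0.8, 100
        totals = []
        for seed in range(k):
            cfg = small_config(
                seed=seed,
                background_hotspot_rate=0.0,
                n_cell_types_dnase=n,
                promoter_presence_prob=p,
            )
            tracks = simulate_hotspots(cfg)
            totals.append(sum(1 for recs in tracks["DNASE"].values() if recs))
        sd = np.sqrt(n * p * (1 - p))
        assert abs(np.mean(totals) - n * p) <= 3 * sd / np.sqrt(k)

    def test_hotspot_lengths_at_least_minimum(self):
        cfg = small_config(hotspot_length_mean=55.0, hotspot_length_sd=40.0)
        tracks = simulate_hotspots(cfg)
        interior = [
            r.end - r.start
            for by in tracks.values()
            for recs in by.values()
            for r in recs
            if r.start > 0 and r.end < cfg.genome_length
        ]
        assert interior and min(interior) >= 50


class TestSimulateCage:
    def test_no_false_rate_all_near_promoters(self):
        cfg = small_config(cage_false_rate=0.0, cage_jitter_sd=20.0)
        preds = simulate_cage(cfg)
        assert preds
        for p in preds:
            assert any(
                abs(p.position - prom.position) <= 4 * cfg.cage_jitter_sd
                and p.strand == prom.strand
                for prom in cfg.planted_promoters
            )

    def test_zero_promoters_only_uniform_noise(self):
        cfg = small_config(planted_promoters=(), cage_false_rate=2.0)
        preds = simulate_cage(cfg)
        assert all(p.cell_type.startswith("CG") for p in preds)

    def test_determinism(self):
        p1 = simulate_cage(small_config())
        p2 = simulate_cage(small_config())
        assert p1 == p2


class TestSimulateEsts:
    def test_error_free_full_length_ests_are_exact_substrings(self):
        cfg = small_config(est_error_rate=0.0, est_length_mean=400.0, est_length_sd=0.0)
        genome, truth = generate_genome(cfg)
        ests, truth = simulate_ests(cfg, genome, truth)
        lnc_fwd = genome[truth.lnc_start : truth.lnc_end]
        for e in ests:
            assert e.sequence in lnc_fwd

    def test_zero_ests_empty(self):
        cfg = small_config(n_ests=0)
        genome, truth = generate_genome(cfg)
        ests, _ = simulate_ests(cfg, genome, truth)
        assert ests == []

    def test_consensus_recovers_hidden_lncrna(self):
        cfg = SynthConfig(seed=11)
        ds = generate_dataset(cfg)
        seqs = [to_transcript_orientation(e) for e in ds.ests]
        consensus = call_consensus(build_msa(seqs), min_depth=2, min_support=0.5)
        match = match_consensus(consensus.sequence, [("lnc", ds.truth.lnc_sequence)])
        assert match.identity >= 0.99

    def test_decoys_carry_host_gene_strand(self):
        cfg = small_config(est_decoy_fraction=0.5)
        genome, truth = generate_genome(cfg)
        ests, _ = simulate_ests(cfg, genome, truth)
        decoys = [e for e in ests if e.accession.startswith("SYN_DECOY")]
        assert len(decoys) == 3
        assert all(e.strand == cfg.host_gene_strand for e in decoys)

    def test_no_antisense_promoter_rejected(self):
        cfg = small_config(planted_promoters=(PlantedPromoter(1200, "-", 2),))
        genome, truth = generate_genome(cfg)
        with pytest.raises(ValueError):
            simulate_ests(cfg, genome, truth)


class TestDatasetIO:
    def test_write_dataset_deterministic_bytes(self, tmp_path):
        ds = generate_dataset(small_config())
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(ds, d1)
        write_dataset(generate_dataset(small_config()), d2)
        for f1 in sorted(d1.rglob("*")):
            if f1.is_file():
                f2 = d2 / f1.relative_to(d1)
                assert f1.read_bytes() == f2.read_bytes()

    def test_config_yaml_roundtrip(self):
        cfg = small_config()
        assert config_from_yaml(config_to_yaml(cfg)) == cfg

    def test_seed_override(self):
        ds = generate_dataset(small_config(), seed=99)
        assert ds.config.seed == 99

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(gc_fraction=1.5)
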