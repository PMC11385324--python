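"""Generators: determinism, structural invariants, fixture parameters."""

import numpy as np
import pandas as pd
import pytest

from scrkit.errors import ConfigError
from scrkit.proteoform import build_readthrough_db, filter_by_score, map_to_isr_region
from scrkit.seqcore import STOP_CODONS, find_isr, translate_extension
from scrkit.synthdata import (
    FIXTURE_NAMES,
    SENSE_CODONS,
    SimConfig,
    make_fixture,
    make_fixture_pair,
    make_ortholog_set,
    make_transcript,
    simulate_footprints,
    simulate_luciferase,
    simulate_peptides,
    spawn_seeds,
)


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cds_len_nt": 7},
            {"isr_len_nt": -3},
            {"isr_len_nt": 80},
            {"theta": 1.5},
            {"noise_cv": -0.1},
            {"n_replicates": 0},
            {"lambda_cds": 0.0},
            {"sub_rate": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)

    def test_sense_codon_pool(self):
        assert len(SENSE_CODONS) == 61
        assert not set(SENSE_CODONS) & STOP_CODONS


class TestMakeTranscript:
    def test_isr_length_is_exact(self):
        t = make_transcript(SimConfig(seed=5, isr_len_nt=81))
        assert find_isr(t).length_nt == 81

    def test_zero_length_isr(self):
        t = make_transcript(SimConfig(seed=5, isr_len_nt=0))
        rec = find_isr(t)
        assert rec.length_nt == 0 and rec.downstream_stop in STOP_CODONS

    def test_seed_determinism(self):
        a = make_transcript(SimConfig(seed=9))
        b = make_transcript(SimConfig(seed=9))
        c = make_transcript(SimConfig(seed=10))
        assert (a.cds, a.utr3) == (b.cds, b.utr3)
        assert (a.cds, a.utr3) != (c.cds, c.utr3)

    def test_invariants_over_random_configs(self):
        """Transcript + ISR invariants hold across 1000 random configurations."""
        rng = np.random.default_rng(13)
        for _ in range(1000):
            cfg = SimConfig(
                seed=int(rng.integers(2**31)),
                cds_len_nt=3 * int(rng.integers(2, 40)),
                isr_len_nt=3 * int(rng.integers(0, 40)),
                distal_len_nt=int(rng.integers(0, 30)),
            )
            t = make_transcript(cfg)
            assert len(t.cds) % 3 == 0 and t.cds[-3:] == "TAA"
            rec = find_isr(t)
            assert rec.length_nt == cfg.isr_len_nt
            assert not rec.open_ended


class TestFixtures:
    def test_fixture_parameters(self, hominini, ancestral, mouse):
        assert find_isr(hominini).length_nt == 81
        assert find_isr(hominini).span_nt == 84
        assert find_isr(mouse).length_nt == 51
        assert translate_extension(find_isr(hominini), "decode_as_X").length_aa == 28
        assert translate_extension(find_isr(mouse), "decode_as_X").length_aa == 18
        # the frameshifted ancestral structure stops well short of 81 nt
        assert find_isr(ancestral).length_nt < 81

    def test_pair_differs_by_single_base_at_53(self):
        anc, hom = make_fixture_pair()
        assert len(hom.utr3) == len(anc.utr3) + 1
        assert hom.utr3[:52] == anc.utr3[:52]
        assert hom.utr3[52] == "T"
        assert hom.utr3[53:] == anc.utr3[52:]

    def test_fixtures_are_deterministic(self):
        for name in FIXTURE_NAMES:
            assert make_fixture(name) == make_fixture(name)

    def test_unknown_fixture(self):
        with pytest.raises(ConfigError):
            make_fixture("gibbon_like")


class TestSimulateLuciferase:
    def test_noiseless_recovery_is_exact(self):
        from scrkit.reporterquant import scr_efficiency

        t = simulate_luciferase(SimConfig(seed=3, theta=0.5, noise_cv=0.0))
        assert scr_efficiency(t).pct == pytest.approx(50.0)
        t0 = simulate_luciferase(SimConfig(seed=3, theta=0.0, noise_cv=0.0))
        assert scr_efficiency(t0).pct == 0.0

    def test_table_shape_and_determinism(self):
        cfg = SimConfig(seed=4, n_replicates=4)
        t = simulate_luciferase(cfg)
        assert list(t.columns) == ["construct", "replicate", "fluc", "rluc"]
        assert len(t) == 8
        pd.testing.assert_frame_equal(t, simulate_luciferase(cfg))


class TestMakeOrthologSet:
    def test_no_substitutions_no_insertion_all_identical(self):
        cfg = SimConfig(seed=6, sub_rate=0.0, insertion_offset=None, n_taxa=5)
        s = make_ortholog_set(cfg)
        seqs = {s.utr3_by_taxon[t] for t in s.taxa}
        assert len(seqs) == 1

    def test_insertion_subset_classification_matches_find_isr(self):
        """Classification of each taxon agrees with a direct per-taxon scan."""
        from scrkit.orthoevo import compare_orthologs
        from scrkit.seqcore import scan_utr

        cfg = SimConfig(seed=8, sub_rate=0.0, n_taxa=6, insertion_offset=53)
        s = make_ortholog_set(cfg, insertion_taxa=s_taxa(6)[:3])
        for row in compare_orthologs(s, threshold_aa=28):
            rec = scan_utr(s.utr3_by_taxon[row.taxon])
            assert row.isr_len_nt == rec.length_nt
            expected_len = rec.length_nt // 3 + 1
            assert row.ext_len_aa == expected_len

    def test_inserted_taxa_carry_one_extra_base(self):
        cfg = SimConfig(seed=8, sub_rate=0.0, n_taxa=4, insertion_offset=10)
        s = make_ortholog_set(cfg, insertion_taxa=["taxon_01"])
        ref = s.utr3_by_taxon["taxon_01"]
        other = s.utr3_by_taxon["taxon_02"]
        assert len(ref) == len(other) + 1 and ref[9] == "T"

    def test_seed_determinism(self):
        cfg = SimConfig(seed=21)
        a, b = make_ortholog_set(cfg), make_ortholog_set(cfg)
        assert a.utr3_by_taxon == b.utr3_by_taxon


def s_taxa(n):
    return [f"taxon_{i + 1:02d}" for i in range(n)]


@pytest.fixture(scope="module")
def db(hominini):
    return build_readthrough_db(hominini)


class TestSimulatePeptides:

    def test_truth_scores_survive_filter_decoys_do_not_match(self, db):
        """After the score filter, no decoy maps inside the extension."""
        for seed in range(5):
            records = simulate_peptides(db, SimConfig(seed=seed), n_decoys=30)
            decoys = [r for r in records if r.source == "decoy"]
            kept = filter_by_score(decoys, 70.0)
            for rec in kept:
                assert map_to_isr_region(rec, db).overlap_class != "extension_internal"

    def test_true_peptides_map_extension_internal(self, db):
        records = simulate_peptides(db, SimConfig(seed=0))
        truths = [r for r in records if r.source == "true_isr"]
        assert truths
        for rec in truths:
            assert map_to_isr_region(rec, db).overlap_class == "extension_internal"

    def test_planted_anchor_score_survives_filter(self, db):
        from scrkit.proteoform import PeptideRecord

        records = simulate_peptides(db, SimConfig(seed=0))
        records.append(PeptideRecord("GLLITDSR", 143.37, source="anchor"))
        kept = filter_by_score(records, 70.0)
        assert any(r.source == "anchor" for r in kept)

    def test_empty_when_nothing_requested(self, db):
        records = simulate_peptides(db, SimConfig(seed=0), n_decoys=0, min_len=999)
        assert records == []


class TestSimulateFootprints:
    def test_theta_one_matches_cds_rate(self, hominini):
        isr = find_isr(hominini)
        cfg = SimConfig(seed=14, theta=1.0, lambda_cds=200.0)
        p = simulate_footprints(hominini, isr, cfg)
        cds = p.counts[: len(hominini.cds) - 3]
        isr_counts = p.counts[len(hominini.cds) : len(hominini.cds) + 81]
        # both Poisson(200); means within a few joint standard errors
        se = np.sqrt(200 / len(cds) + 200 / len(isr_counts))
        assert abs(cds.mean() - isr_counts.mean()) < 5 * se

    def test_theta_zero_no_background_gives_silent_utr(self, hominini):
        isr = find_isr(hominini)
        cfg = SimConfig(seed=14, theta=0.0, distal_lambda=0.0)
        p = simulate_footprints(hominini, isr, cfg)
        assert p.counts[len(hominini.cds) :].sum() == 0

    def test_ratio_recovers_theta_within_sampling_error(self, hominini):
        from scrkit.ribosignal import region_densities

        isr = find_isr(hominini)
        vals = []
        for seed in spawn_seeds(55, 20):
            cfg = SimConfig(seed=seed, theta=0.2, lambda_cds=100.0)
            sig = region_densities(simulate_footprints(hominini, isr, cfg), hominini, isr)
            vals.append(sig.ratio)
        assert abs(np.mean(vals) - 0.2) < 0.02


class TestSpawnSeeds:
    def test_reproducible_and_bounded(self):
        a, b = spawn_seeds(99, 10), spawn_seeds(99, 10)
        assert a == b and all(0 <= s < 2**31 for s in a)
        assert spawn_seeds(100, 10) != a
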