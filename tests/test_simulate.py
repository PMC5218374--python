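"""Simulator ground truth: planted divergence, pool bookkeeping, reads."""

import numpy as np
import pytest

import rdnahomeo as r


class TestProgenitorPair:
    def test_full_unit_divergence_plants_72_sites(self):
        cfg = r.SimConfig(unit_length=5803, divergence=0.0124, seed=3)
        A, C, sites = r.make_progenitor_pair(cfg)
        assert len(sites) == 72
        diffs = [i for i, (a, c) in enumerate(zip(A.sequence, C.sequence)) if a != c]
        assert diffs == sorted(s.position for s in sites)
        for s in sites:
            assert A.sequence[s.position] == s.allele_A
            assert C.sequence[s.position] == s.allele_C

    def test_zero_divergence_identical(self):
        cfg = r.SimConfig(divergence=0.0, seed=1)
        A, C, sites = r.make_progenitor_pair(cfg)
        assert sites == []
        assert A.sequence == C.sequence

    @pytest.mark.parametrize("seed", [0, 11])
    def test_site_count_and_determinism(self, seed):
        cfg = r.SimConfig(unit_length=1000, divergence=0.01, read_length=90,
                          seed=seed)
        _, _, s1 = r.make_progenitor_pair(cfg)
        _, _, s2 = r.make_progenitor_pair(cfg)
        assert len(s1) == 10
        assert [x.position for x in s1] == [x.position for x in s2]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            r.SimConfig(divergence=1.5)
        with pytest.raises(ValueError):
            r.SimConfig(unit_length=50, read_length=100)
        with pytest.raises(ValueError):
            r.SimConfig(error_rate=0.5)

    def test_features_within_unit_and_disjoint(self, progenitors):
        A, _, _ = progenitors
        ivals = sorted(A.features.values())
        assert all(0 <= s < e <= len(A) for s, e in ivals)
        assert all(b[0] >= a[1] for a, b in zip(ivals, ivals[1:]))


class TestAllopolyploidPool:
    def test_additive_pool_counts(self, progenitors, small_cfg):
        A, C, sites = progenitors
        pool = r.make_allopolyploid_pool(A, C, sites, small_cfg)
        assert pool.label_counts() == {"A": 1700, "C": 1160}
        assert pool.size == 2860

    def test_conversion_65_percent(self, progenitors, small_cfg):
        A, C, sites = progenitors
        cfg = small_cfg.with_(conversion_fraction=0.65)
        pool = r.make_allopolyploid_pool(A, C, sites, cfg)
        counts = pool.label_counts()
        assert counts["C"] == 1160 - round(0.65 * 1160) == 406
        assert counts["C_converted"] == 754
        assert pool.size == 2860
        assert pool.c_unit_fraction() == pytest.approx(406 / 2860)

    def test_full_conversion_monomorphic_at_diagnostics(self, progenitors, small_cfg):
        A, C, sites = progenitors
        pool = r.make_allopolyploid_pool(A, C, sites,
                                         small_cfg.with_(conversion_fraction=1.0))
        assert "C" not in pool.label_counts()
        for entry in pool.entries:
            for s in sites:
                assert entry.sequence[s.position] == s.allele_A

    def test_converted_units_match_a_sequence_at_diagnostics(self, progenitors,
                                                             small_cfg):
        A, C, sites = progenitors
        cfg = small_cfg.with_(conversion_fraction=0.5)
        pool = r.make_allopolyploid_pool(A, C, sites, cfg)
        for entry in pool.entries:
            if entry.label == "C_converted":
                for s in sites:
                    assert entry.sequence[s.position] == s.allele_A

    def test_mutated_family_at_nondiagnostic_positions(self, progenitors, small_cfg):
        A, C, sites = progenitors
        cfg = small_cfg.with_(unique_rate=0.3)
        pool = r.make_allopolyploid_pool(A, C, sites, cfg)
        counts = pool.label_counts()
        assert counts.get("mutated", 0) > 0
        assert pool.size == 2860
        diag = {s.position for s in sites}
        for entry in pool.entries:
            if entry.label == "mutated":
                novel = [i for i, (x, y) in
                         enumerate(zip(entry.sequence, A.sequence)) if x != y]
                assert novel  # carries novel variants
                assert not set(novel) & diag

    def test_empty_pool_rejected(self, progenitors):
        A, C, sites = progenitors
        cfg = r.SimConfig(unit_length=1200, n_A=0, n_C=0)
        with pytest.raises(ValueError):
            r.make_allopolyploid_pool(A, C, sites, cfg)


class TestReads:
    def test_fastq_byte_determinism(self, progenitors, small_cfg):
        A, C, sites = progenitors
        pool = r.make_allopolyploid_pool(A, C, sites, small_cfg)
        r1 = r.simulate_reads(pool, small_cfg).to_fastq_string()
        r2 = r.simulate_reads(pool, small_cfg).to_fastq_string()
        assert r1 == r2
        r3 = r.simulate_reads(pool, small_cfg.with_(seed=8)).to_fastq_string()
        assert r1 != r3

    def test_error_free_reads_are_unit_substrings(self, progenitors, small_cfg):
        A, _, sites = progenitors
        uniform = r.UnitConsensus("A", A.sequence, A.features)  # no minor haplotype
        pool = r.make_progenitor_pool(uniform, 100, small_cfg)
        reads = r.simulate_reads(pool, small_cfg.with_(coverage=5.0))
        unit = A.sequence
        from rdnahomeo.simulate import revcomp

        for _, seq, qual in reads:
            assert seq in unit or revcomp(seq) in unit
            assert set(qual) == {"I"}

    def test_background_dilution_hits_target_proportion(self, progenitors, small_cfg):
        A, C, sites = progenitors
        pool = r.make_allopolyploid_pool(A, C, sites, small_cfg)
        cfg = small_cfg.with_(coverage=20.0, target_genome_proportion=0.2)
        reads = r.simulate_reads(pool, cfg)
        n_rdna = sum(1 for i in reads.ids if i.startswith("sim"))
        assert n_rdna / len(reads) == pytest.approx(0.2, abs=0.01)

    def test_read_set_is_valid(self, progenitors, small_cfg):
        A, C, sites = progenitors
        pool = r.make_allopolyploid_pool(A, C, sites, small_cfg)
        reads = r.simulate_reads(pool, small_cfg.with_(coverage=2.0))
        reads.validate()


class TestAmplicons:
    def test_two_haplotype_pool_fractions(self, progenitors, small_cfg):
        A, C, sites = progenitors
        pool = r.UnitPool(
            [r.PoolEntry(A.sequence, "A", 800), r.PoolEntry(C.sequence, "C", 200)],
            small_cfg.unit_length,
        )
        region = (0, small_cfg.unit_length)  # spans all diagnostic sites
        reads = r.simulate_amplicons(pool, region, 1000, small_cfg)
        a_extract = A.sequence[region[0]: region[1]]
        frac_a = sum(1 for _, s, _ in reads if s == a_extract) / len(reads)
        assert frac_a == pytest.approx(0.8, abs=0.04)

    def test_single_source_pool(self, progenitors, small_cfg):
        A, _, _ = progenitors
        pool = r.UnitPool([r.PoolEntry(A.sequence, "A", 5)], small_cfg.unit_length)
        reads = r.simulate_amplicons(pool, (0, 150), 50, small_cfg)
        assert set(reads.sequences) == {A.sequence[:150]}

    def test_degenerate_inputs_rejected(self, progenitors, small_cfg):
        A, _, _ = progenitors
        pool = r.UnitPool([r.PoolEntry(A.sequence, "A", 5)], small_cfg.unit_length)
        with pytest.raises(ValueError):
            r.simulate_amplicons(pool, (0, 150), 0, small_cfg)
        with pytest.raises(ValueError):
            r.simulate_amplicons(pool, (0, small_cfg.unit_length + 10), 10, small_cfg)
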