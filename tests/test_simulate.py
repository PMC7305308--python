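"""Simulator: determinism, transcript validity, coverage arithmetic, mixtures."""

import numpy as np
import pytest

from cdr3kit.germline import GermlineIndex, translate_nt
from cdr3kit.simulate import (
    SimConfig,
    SimulatedTranscript,
    make_mixture,
    simulate_reads,
    simulate_transcripts,
    synthetic_germline,
    truth_manifest,
)

from .oracle import oracle_best_candidate


class TestGermlineFixture:
    def test_deterministic(self):
        a = synthetic_germline(0)
        b = synthetic_germline(0)
        assert [(s.id, s.nt_seq) for s in a] == [(s.id, s.nt_seq) for s in b]

    def test_anchor_anatomy(self):
        for seg in synthetic_germline(0):
            if seg.segment_class == "V":
                assert seg.aa_seq[seg.anchor_pos] == "C"
                assert "C" not in seg.aa_seq[seg.anchor_pos + 1 :]
            elif seg.segment_class == "J":
                anchor = "W" if seg.chain == "IGH" else "F"
                assert seg.aa_seq[seg.anchor_pos] == anchor
                assert anchor not in seg.aa_seq[: seg.anchor_pos]


class TestTranscripts:
    def test_determinism(self, fixture_index):
        cfg = SimConfig(seed=9, n_transcripts=10)
        a = simulate_transcripts(cfg, fixture_index)
        b = simulate_transcripts(cfg, fixture_index)
        assert [t.full_nt for t in a] == [t.full_nt for t in b]
        assert [t.abundance for t in a] == [t.abundance for t in b]

    def test_composition_invariant(self, fixture_index):
        cfg = SimConfig(seed=9, n_transcripts=15)
        segs = {
            (s.chain, s.segment_class, s.id): s for s in synthetic_germline(0)
        }
        for tx in simulate_transcripts(cfg, fixture_index):
            v = segs[(tx.chain, "V", tx.v_id)]
            j = segs[(tx.chain, "J", tx.j_id)]
            middle = tx.n1_nt + (
                segs[(tx.chain, "D", tx.d_id)].nt_seq if tx.d_id else ""
            ) + tx.n2_nt
            assert tx.full_nt == v.nt_seq + middle + j.nt_seq
            assert tx.true_cdr3_aa[0] == "C"
            assert tx.true_cdr3_aa[-1] == ("W" if tx.chain == "IGH" else "F")
            assert "*" not in translate_nt(tx.full_nt)[: tx.cdr3_end // 3]

    def test_true_cdr3_recovered_by_independent_oracle(self, igh_index):
        cfg = SimConfig(seed=4, n_transcripts=6, chains=("IGH",))
        for tx in simulate_transcripts(cfg, igh_index):
            found = oracle_best_candidate(tx.full_nt, igh_index)
            assert found is not None
            assert found[1] == tx.true_cdr3_aa

    def test_exponent_zero_uniform_abundances(self, fixture_index):
        cfg = SimConfig(seed=2, n_transcripts=8, power_exponent=0.0)
        txs = simulate_transcripts(cfg, fixture_index)
        assert np.allclose([t.abundance for t in txs], 1 / 8)

    def test_abundances_normalised_and_rank_ordered(self, fixture_index):
        cfg = SimConfig(seed=2, n_transcripts=20, power_exponent=1.0)
        abundances = [t.abundance for t in simulate_transcripts(cfg, fixture_index)]
        assert sum(abundances) == pytest.approx(1.0)
        assert abundances == sorted(abundances, reverse=True)


class TestReads:
    def test_coverage_arithmetic_single_transcript(self, fixture_index):
        tx = SimulatedTranscript(
            id="t", chain="IGH", v_id="v", d_id=None, j_id="j",
            n1_nt="", n2_nt="", full_nt="ACGT" * 75, true_cdr3_aa="CW",
            cdr3_start=0, cdr3_end=6, junction_start=100, junction_end=120,
            abundance=1.0,
        )
        cfg = SimConfig(seed=1, n_transcripts=1, read_length=75, coverage=8,
                        error_rate=0.0)
        reads = simulate_reads([tx], cfg)
        # 16 fragments x 2 mates: per-base depth 32*75/300 = 8
        assert len(reads) == 32
        assert all(len(r.seq) == 75 for r in reads)

    def test_same_seed_byte_identical(self, fixture_index):
        cfg = SimConfig(seed=6, n_transcripts=10, read_length=50, coverage=4)
        txs = simulate_transcripts(cfg, fixture_index)
        a = simulate_reads(txs, cfg)
        b = simulate_reads(txs, cfg)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_junction_flags_match_interval_recount(self, fixture_index):
        cfg = SimConfig(seed=6, n_transcripts=10, read_length=50, coverage=4)
        txs = simulate_transcripts(cfg, fixture_index)
        by_id = {t.id: t for t in txs}
        for read in simulate_reads(txs, cfg):
            tx = by_id[read.transcript_id]
            expected = (
                read.start < tx.junction_end
                and tx.junction_start < read.start + len(read.seq)
            )
            assert read.contains_junction == expected

    def test_degenerate_error_rate_still_legal_reads(self, fixture_index):
        cfg = SimConfig(seed=6, n_transcripts=5, read_length=50, coverage=2,
                        error_rate=0.5)
        txs = simulate_transcripts(cfg, fixture_index)
        for read in simulate_reads(txs, cfg):
            assert len(read.seq) == 50
            assert set(read.seq) <= set("ACGT")

    def test_errors_change_bases_at_requested_rate(self, fixture_index):
        from cdr3kit.germline import revcomp

        cfg = SimConfig(seed=6, n_transcripts=5, read_length=75, coverage=4,
                        error_rate=0.05)
        txs = simulate_transcripts(cfg, fixture_index)
        by_id = {t.id: t for t in txs}
        diffs = total = 0
        for read in simulate_reads(txs, cfg):
            tx = by_id[read.transcript_id]
            clean = tx.full_nt[read.start : read.start + len(read.seq)]
            if read.mate == 2:
                clean = revcomp(clean)
            diffs += sum(a != b for a, b in zip(clean, read.seq))
            total += len(read.seq)
        assert 0.02 < diffs / total < 0.1


class TestMixture:
    def test_ratio_counting(self, fixture_index):
        cfg = SimConfig(seed=6, n_transcripts=3, read_length=50, coverage=1,
                        mixture_ratio=10)
        txs = simulate_transcripts(cfg, fixture_index)
        reads = simulate_reads(txs, cfg)[:10]
        mix = make_mixture(reads, cfg)
        assert len(mix) == 110
        assert sum(r.transcript_id is not None for r in mix) == 10

    def test_ratio_zero_passthrough(self, fixture_index):
        cfg = SimConfig(seed=6, n_transcripts=3, read_length=50, coverage=1,
                        mixture_ratio=0)
        txs = simulate_transcripts(cfg, fixture_index)
        reads = simulate_reads(txs, cfg)
        mix = make_mixture(reads, cfg)
        assert sorted(r.id for r in mix) == sorted(r.id for r in reads)

    def test_receptor_ids_preserved_in_manifest(self, fixture_index):
        cfg = SimConfig(seed=8, n_transcripts=5, read_length=50, coverage=2,
                        mixture_ratio=5)
        txs = simulate_transcripts(cfg, fixture_index)
        reads = simulate_reads(txs, cfg)
        manifest = truth_manifest(txs, reads)
        mix_ids = {r.id for r in make_mixture(reads, cfg)}
        assert set(manifest["read_id"]) <= mix_ids
        assert len(manifest) == len(reads)

    def test_mixture_deterministic(self, fixture_index):
        cfg = SimConfig(seed=8, n_transcripts=3, read_length=50, coverage=1,
                        mixture_ratio=20)
        txs = simulate_transcripts(cfg, fixture_index)
        reads = simulate_reads(txs, cfg)
        a = make_mixture(reads, cfg)
        b = make_mixture(reads, cfg)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]


def test_noiseless_recovery_recall_is_one(igh_index):
    """Error-free reads at ample coverage recover every distinct CDR3."""
    from cdr3kit.evaluate import _as_candidates, score
    from cdr3kit.pipeline import run_pipeline

    cfg = SimConfig(
        seed=12, n_transcripts=25, chains=("IGH",), read_length=100,
        coverage=16, error_rate=0.0, abundance_weighted=False,
    )
    txs = simulate_transcripts(cfg, igh_index)
    reads = simulate_reads(txs, cfg)
    result = run_pipeline(_as_candidates(reads), igh_index)
    ev = score(result.clonotype_set("IGH"), {t.true_cdr3_aa for t in txs})
    assert ev.recall == 1.0
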