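"""Stage-1 / stage-2 CDR3 assembly, checked against a brute-force oracle."""

import random

import pytest

from cdr3kit.assembly import (
    GermlineKmerScreen,
    classify_partials,
    match_j,
    match_v,
    scan_putative_cdr3,
    six_frame_translate,
    stage1_assemble,
    stage2_merge,
)
from cdr3kit.germline import GermlineIndex, revcomp
from cdr3kit.intake import CandidateRead

from .oracle import oracle_best_candidate


def cr(seq, read_id="r1"):
    return CandidateRead(read_id=read_id, nt_seq=seq, origin="direct_fastq")


class TestTranslation:
    def test_frame0(self):
        assert six_frame_translate("TGTGCT")[0] == "CA"

    def test_reverse_strand(self):
        # revcomp("AGCACA") == "TGTGCT" -> "CA" in reverse frame 0
        assert six_frame_translate("AGCACA")[3] == "CA"

    def test_stop_codon(self):
        assert six_frame_translate("TGA")[0] == "*"

    def test_six_frames_consistent(self):
        nt = "TGTGCTAGACTGGGG"
        frames = six_frame_translate(nt)
        assert len(frames) == 6
        assert frames[3:] == six_frame_translate(revcomp(nt))[:3]


class TestScan:
    def test_single_span(self):
        assert scan_putative_cdr3("GGCARDYWGG", "IGH") == [(2, 7)]

    def test_length_bound_excludes_short_span(self):
        # spans (0,3) keeps length 4; (2,3) rejected below the 4 aa floor
        assert scan_putative_cdr3("CACW", "IGH") == [(0, 3)]

    def test_stop_inside_span_excluded(self):
        assert scan_putative_cdr3("GCAR*DYWGG", "IGH") == []
        assert scan_putative_cdr3("GCAR*DYWGG", "IGH", allow_stop=True) == [(1, 7)]

    def test_light_chain_terminal_is_f(self):
        assert scan_putative_cdr3("GCARDYFGG", "IGK") == [(1, 6)]
        assert scan_putative_cdr3("GCARDYFGG", "IGH") == []


class TestMatchRules:
    V_ENTRIES = [("V1", "SSYYYQS"), ("V2", "SSYYAAA")]
    J_ENTRIES = [("J1", "GQGTLVT"), ("J2", "AAAALVT")]

    def test_exact_prefix_match(self):
        assert match_v("YYYQS", self.V_ENTRIES) == ["V1"]

    def test_one_mismatch_tolerated(self):
        assert match_v("YYYQA", self.V_ENTRIES) == ["V1"]

    def test_prefix_of_four_rejected_regardless_of_distance(self):
        assert match_v("YYQS", self.V_ENTRIES) == []

    def test_all_equally_best_reported(self):
        entries = [("Va", "SSYYYQS"), ("Vb", "TSYYYQS")]
        assert match_v("YYYQS", entries) == ["Va", "Vb"]

    def test_j_exact_and_mismatch(self):
        assert match_j("GQGTL", self.J_ENTRIES) == ["J1"]
        assert match_j("GQGTA", self.J_ENTRIES) == ["J1"]

    def test_j_suffix_of_three_rejected(self):
        assert match_j("GQG", self.J_ENTRIES) == []


def planted_read(index, chain="IGH", v=0, j=0, core_extra="DGSY", flank=6):
    """Construct an error-free read containing a full CDR3 with context."""
    vseg = index.v_segments[chain][v]
    jseg = index.j_segments[chain][j]
    v_nt = vseg.nt_seq
    j_nt = jseg.nt_seq
    insert = {"D": "GAT", "G": "GGT", "S": "TCT", "Y": "TAT"}
    middle = "".join(insert[a] for a in core_extra)
    read = v_nt[-(3 * (flank + 3)) :] + middle + j_nt[: 3 * (flank + 3)]
    core = (
        vseg.aa_seq[vseg.anchor_pos :]
        + core_extra
        + jseg.aa_seq[: jseg.anchor_pos + 1]
    )
    return read, core, vseg.id, jseg.id


class TestStage1:
    def test_planted_exact_read_recovered(self, igh_index):
        read, core, v_id, j_id = planted_read(igh_index)
        (cand,) = stage1_assemble([cr(read)], igh_index)
        assert cand.core_aa == core
        assert v_id in cand.v_hits
        assert j_id in cand.j_hits
        assert cand.chain == "IGH"

    def test_planted_read_with_substitution_recovered(self, igh_index):
        read, core, v_id, j_id = planted_read(igh_index)
        mutated = "A" + read[1:] if read[0] != "A" else "C" + read[1:]
        (cand,) = stage1_assemble([cr(mutated)], igh_index)
        assert cand.core_aa == core

    def test_random_read_yields_nothing(self, igh_index):
        rng = random.Random(11)
        read = "".join(rng.choice("ACGT") for _ in range(100))
        assert oracle_best_candidate(read, igh_index) is None
        assert stage1_assemble([cr(read)], igh_index) == []

    def test_reverse_complement_read_recovered(self, igh_index):
        read, core, _, _ = planted_read(igh_index)
        (cand,) = stage1_assemble([cr(revcomp(read))], igh_index)
        assert cand.core_aa == core

    def test_core_starts_c_ends_chain_residue(self, fixture_index):
        for chain in ("IGH", "IGK"):
            read, core, _, _ = planted_read(fixture_index, chain=chain)
            (cand,) = stage1_assemble([cr(read)], fixture_index)
            assert cand.core_aa[0] == "C"
            assert cand.core_aa[-1] == ("W" if chain == "IGH" else "F")

    def test_one_candidate_max_per_read(self, igh_index):
        read, _, _, _ = planted_read(igh_index)
        cands = stage1_assemble([cr(read + read, "double")], igh_index)
        assert len(cands) <= 1


class TestOracleEquivalence:
    """stage1_assemble must agree with exhaustive DP enumeration."""

    @pytest.fixture(scope="class")
    @staticmethod
    def small_index(fixture_segments):
        segs = [
            s for s in fixture_segments
            if s.chain == "IGH" and s.segment_class in ("V", "J")
        ]
        return GermlineIndex.build(segs[:3] + segs[-2:])  # <= 5 segments

    def make_reads(self, index, n, seed):
        rng = random.Random(seed)
        reads = []
        for i in range(n):
            kind = rng.random()
            if kind < 0.4:
                v = rng.randrange(len(index.v_segments["IGH"]))
                j = rng.randrange(len(index.j_segments["IGH"]))
                extra = "".join(rng.choice("DGSY") for _ in range(rng.randrange(1, 8)))
                read, _, _, _ = planted_read(
                    index, v=v, j=j, core_extra=extra, flank=rng.randrange(0, 8)
                )
            elif kind < 0.7:
                read, _, _, _ = planted_read(index)
                pos = rng.randrange(len(read))
                read = read[:pos] + rng.choice("ACGT") + read[pos + 1 :]
            else:
                read = "".join(rng.choice("ACGT") for _ in range(75))
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(cr(read, f"r{i}"))
        return reads

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_agreement_on_small_instances(self, small_index, seed):
        reads = self.make_reads(small_index, 50, seed)
        got = {c.read_id: c for c in stage1_assemble(reads, small_index)}
        for read in reads:
            expected = oracle_best_candidate(read.nt_seq, small_index)
            if expected is None:
                assert read.read_id not in got
            else:
                chain, core, v_ids, j_ids = expected
                cand = got[read.read_id]
                assert (cand.chain, cand.core_aa) == (chain, core)
                assert cand.v_hits == v_ids
                assert cand.j_hits == j_ids


class TestStage2:
    def split_read_pair(self, index, overlap=15):
        vseg = index.v_segments["IGH"][0]
        jseg = index.j_segments["IGH"][0]
        middle = "GATTACGGTAGCTATGATCGA"  # 21 nt junction
        tx = vseg.nt_seq + middle + jseg.nt_seq
        junction_mid = len(vseg.nt_seq) + len(middle) // 2
        v_read = tx[junction_mid - 50 : junction_mid + overlap - 25]
        j_read = tx[junction_mid - 25 : junction_mid + 50]
        # v_read suffix and j_read prefix share `overlap` nt by construction
        assert v_read[-overlap:] == j_read[:overlap]
        core = oracle_best_candidate(tx, index)[1]
        return v_read, j_read, core

    def test_merge_recovers_planted_junction(self, igh_index):
        v_read, j_read, core = self.split_read_pair(igh_index, overlap=15)
        v_only, j_only, full = classify_partials(
            [cr(v_read, "v1"), cr(j_read, "j1")], igh_index
        )
        assert full == []
        merged = stage2_merge(v_only, j_only, igh_index)
        assert [c.core_aa for c in merged] == [core]

    def test_overlap_of_14_not_merged(self, igh_index):
        v_read, j_read, _ = self.split_read_pair(igh_index, overlap=14)
        v_only, j_only, _ = classify_partials(
            [cr(v_read, "v1"), cr(j_read, "j1")], igh_index
        )
        assert stage2_merge(v_only, j_only, igh_index) == []

    def test_no_j_side_reads_empty_result(self, igh_index):
        v_read, _, _ = self.split_read_pair(igh_index)
        v_only, _, _ = classify_partials([cr(v_read, "v1")], igh_index)
        assert stage2_merge(v_only, [], igh_index) == []

    def test_stage2_extends_but_never_removes_stage1(self, igh_index):
        full_read, core, _, _ = planted_read(igh_index)
        v_read, j_read, _ = self.split_read_pair(igh_index)
        reads = [cr(full_read, "full"), cr(v_read, "v1"), cr(j_read, "j1")]
        v_only, j_only, stage1 = classify_partials(reads, igh_index)
        with_stage2 = stage1 + stage2_merge(v_only, j_only, igh_index)
        stage1_cores = {(c.read_id, c.core_aa) for c in stage1}
        assert stage1_cores <= {(c.read_id, c.core_aa) for c in with_stage2}
        assert len(with_stage2) > len(stage1)


def test_kmer_screen_separates_germline_from_random(igh_index):
    screen = GermlineKmerScreen(igh_index)
    read, _, _, _ = planted_read(igh_index)
    assert screen.hits(read)
    assert screen.hits(revcomp(read))
    rng = random.Random(5)
    false_hits = sum(
        screen.hits("".join(rng.choice("ACGT") for _ in range(75)))
        for _ in range(500)
    )
    assert false_hits <= 5
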