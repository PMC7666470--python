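"""Mutational-mechanism cascade: VNTR -> NAHR -> TE -> NH."""

import numpy as np
import pytest
from pyfaidx import Fasta

from insertag import simulate
from insertag.mechanism import (
    NAHR,
    NH,
    TE,
    VNTR,
    classify_mechanism,
    classify_te,
    detect_nahr,
    detect_vntr,
    extract_breakpoint_context,
    motif_annotator,
    tandem_coverage,
)

from conftest import random_dna


@pytest.fixture(scope="module")
def reference(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("mech")
    genome = simulate.generate_synthetic_genome(20_000, seed=9, repeat_density=0.0)
    path = simulate.write_fasta(str(tmp / "ref.fa"), {"chr1": genome})
    return Fasta(path, as_raw=True, sequence_always_upper=True), genome


class TestContext:
    def test_flanks_are_w_bp_each_side(self, reference):
        ref, genome = reference
        left, right, trunc = extract_breakpoint_context("chr1", 1000, ref, w=100)
        assert left == genome[900:1000]
        assert right == genome[1000:1100]
        assert not trunc

    def test_edge_truncation_flagged(self, reference):
        ref, genome = reference
        left, right, trunc = extract_breakpoint_context("chr1", 50, ref, w=100)
        assert left == genome[:50]
        assert trunc

    def test_flanks_reconstruct_local_reference(self, reference):
        ref, genome = reference
        left, right, _ = extract_breakpoint_context("chr1", 5000, ref, w=100)
        assert left + right == genome[4900:5100]


class TestVNTR:
    def test_constructed_tandem_next_to_motif_run(self):
        flanks = (random_dna(80, np.random.default_rng(0)) + "ACGT", random_dna(100, np.random.default_rng(1)))
        got = detect_vntr("ACGT" * 20, flanks)
        assert got == (4, 20)

    def test_random_sequence_is_not_tandem(self, rng):
        flanks = (random_dna(100, rng), random_dna(100, rng))
        assert detect_vntr(random_dna(400, rng), flanks) is None

    def test_mutated_tandem_matches_exhaustive_period_scan(self, rng):
        motif = "ACGTACG"
        seq = list(motif * 30)
        for j in np.nonzero(rng.random(len(seq)) < 0.05)[0]:
            seq[j] = "ACGT"[("ACGT".index(seq[j]) + 1) % 4]
        seq = "".join(seq)
        flanks = (random_dna(90, rng) + motif, random_dna(100, rng))
        got = detect_vntr(seq, flanks, min_coverage=0.85)
        # brute-force oracle: max tandem coverage over all periods
        best = max(
            range(2, len(seq) // 2 + 1),
            key=lambda p: tandem_coverage(seq, p),
        )
        if got is not None:
            assert tandem_coverage(seq, got[0]) >= 0.85
            assert got[0] <= best or tandem_coverage(seq, best) < 0.85
        else:
            assert all(
                tandem_coverage(seq, p) < 0.85 or motif not in flanks[0][-4 * p:] + flanks[1][:4 * p]
                for p in range(2, len(seq) // 2 + 1)
            )


class TestNAHR:
    def test_identical_terminal_block(self, rng):
        block = random_dna(80, rng)
        left = random_dna(20, rng) + block
        right = block + random_dna(20, rng)
        assert detect_nahr(left, right) == 80

    def test_unrelated_flanks(self, rng):
        assert detect_nahr(random_dna(100, rng), random_dna(100, rng)) is None

    def test_diverged_block_matches_alignment_oracle(self, rng):
        from Bio import Align

        block = list(random_dna(60, rng))
        b2 = list(block)
        for j in (5, 20, 25, 31, 40, 44, 50, 58, 12):  # 9/60 = 15% divergence
            b2[j] = "ACGT"[("ACGT".index(b2[j]) + 1) % 4]
        left = random_dna(40, rng) + "".join(block)
        right = "".join(b2) + random_dna(40, rng)
        got = detect_nahr(left, right, min_homology=50, min_identity=0.9)
        aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                        mismatch_score=-1, open_gap_score=-5,
                                        extend_gap_score=-1)
        aln = aligner.align(left, right)[0]
        span = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
        ident = aln.counts().identities / max(1, span)
        oracle = span >= 50 and ident >= 0.9
        assert (got is not None) == oracle

    def test_block_at_ninety_percent_identity_detected(self, rng):
        block = list(random_dna(100, rng))
        b2 = list(block)
        for j in range(0, 100, 20):  # 5/100 = 5% divergence
            b2[j] = "ACGT"[("ACGT".index(b2[j]) + 1) % 4]
        assert detect_nahr(random_dna(30, rng) + "".join(block),
                           "".join(b2) + random_dna(30, rng)) is not None


class TestTE:
    def test_annotated_alu_like_fraction(self):
        got = classify_te(300, [(5, 295, "Alu")])
        assert got is not None
        assert got[0] == pytest.approx(290 / 300)
        assert got[1] == "Alu"

    def test_half_covered_is_not_te(self):
        assert classify_te(300, [(0, 150, "Alu")]) is None

    def test_exactly_eighty_percent_is_not_te(self):
        # "more than 80%": the boundary itself does not qualify
        assert classify_te(300, [(0, 240, "L1")]) is None
        assert classify_te(300, [(0, 241, "L1")]) is not None

    def test_union_of_overlapping_intervals_matches_per_base_count(self, rng):
        for _ in range(30):
            svlen = int(rng.integers(50, 400))
            n = int(rng.integers(1, 6))
            iv = []
            for _ in range(n):
                s = int(rng.integers(0, svlen - 1))
                e = int(rng.integers(s + 1, svlen + 1))
                iv.append((s, e, "Alu"))
            mask = np.zeros(svlen, dtype=bool)
            for s, e, _ in iv:
                mask[s:e] = True
            got = classify_te(svlen, iv, min_fraction=0.0)
            assert got[0] == pytest.approx(mask.sum() / svlen)

    def test_fraction_invariant_under_interval_splitting(self):
        whole = classify_te(300, [(0, 280, "Alu")], min_fraction=0.0)
        split = classify_te(
            300, [(0, 100, "Alu"), (100, 200, "Alu"), (200, 280, "Alu")],
            min_fraction=0.0,
        )
        assert whole[0] == split[0]

    def test_missing_annotation_falls_through(self):
        assert classify_te(300, []) is None


class TestCascade:
    def test_vntr_beats_te_annotation(self):
        """A tandem insertion fully annotated as TE is still called VNTR."""
        flanks = (random_dna(90, np.random.default_rng(0)) + "ACGTAC", random_dna(100, np.random.default_rng(1)))
        ins = "ACGTAC" * 30
        call = classify_mechanism("v1", ins, flanks, [(0, len(ins), "Alu")])
        assert call.mech == VNTR

    def test_nahr_from_homologous_flanks(self, rng):
        block = random_dna(70, rng)
        call = classify_mechanism(
            "v2", random_dna(500, rng),
            (random_dna(30, rng) + block, block + random_dna(30, rng)),
        )
        assert call.mech == NAHR
        assert call.evidence["homology_len"] >= 50

    def test_te_from_annotation(self, rng):
        ins = random_dna(300, rng)
        call = classify_mechanism(
            "v3", ins, (random_dna(100, rng), random_dna(100, rng)),
            [(0, 290, "L1")],
        )
        assert call.mech == TE

    def test_no_features_is_nh(self, rng):
        call = classify_mechanism(
            "v4", random_dna(300, rng),
            (random_dna(100, rng), random_dna(100, rng)),
        )
        assert call.mech == NH

    def test_cascade_equals_ordered_detectors(self, rng):
        """Random constructed panel: label equals first positive detector."""
        for i in range(20):
            ins = random_dna(int(rng.integers(60, 400)), rng)
            flanks = (random_dna(100, rng), random_dna(100, rng))
            ann = [(0, int(0.95 * len(ins)), "Alu")] if rng.random() < 0.5 else []
            call = classify_mechanism(f"r{i}", ins, flanks, ann)
            v = detect_vntr(ins, flanks)
            h = detect_nahr(flanks[0], flanks[1])
            t = classify_te(len(ins), ann)
            expected = VNTR if v else NAHR if h else TE if t else NH
            assert call.mech == expected


def test_motif_annotator_finds_library_elements(rng):
    lib = {"AluSyn": random_dna(300, rng)}
    ins = random_dna(50, rng) + lib["AluSyn"] + random_dna(40, rng)
    iv = motif_annotator(ins, lib)
    assert len(iv) == 1
    s, e, name = iv[0]
    assert (s, e, name) == (50, 350, "AluSyn")
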