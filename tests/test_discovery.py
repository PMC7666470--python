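"""Clustering, breakpoint refinement, and tag pairing."""

import itertools

import numpy as np

from insertag.assembly import Contig
from insertag.discovery import (
    LEFT,
    RIGHT,
    InsertionTag,
    cluster_pers,
    pair_insertion_tags,
    refine_breakpoint,
    validate_contig,
)
from insertag.io_alignments import DiscordantPER, LibraryStats

from conftest import random_dna


def per_at(pos: int, strand: str = "+", chrom: str = "chr1") -> DiscordantPER:
    return DiscordantPER(
        anchor_chrom=chrom, anchor_pos=pos, anchor_strand=strand,
        anchor_cigar="100M", anchor_mapq=60, anchor_seq="A" * 100,
        mate_seq="C" * 100, mate_status="unmapped", qname=f"q{pos}{strand}",
    )


LIB = LibraryStats(mean_insert=300, sd_insert=0, read_length=100)  # window 300


class TestClustering:
    def test_all_within_window_one_cluster(self):
        pers = [per_at(p) for p in (100, 150, 200)]
        (cl,) = cluster_pers(pers, LIB, min_support=3)
        assert cl.n_support == 3
        assert (cl.start, cl.end) == (100, 201)

    def test_gap_exceeding_window_splits(self):
        pers = [per_at(p) for p in (100, 5000, 5100, 5200)]
        clusters = cluster_pers(pers, LIB, min_support=1)
        assert [c.n_support for c in clusters] == [1, 3]

    def test_strands_partition_clusters(self):
        pers = [per_at(100, "+"), per_at(120, "-"), per_at(140, "+"), per_at(160, "-"), per_at(180, "+")]
        clusters = cluster_pers(pers, LIB, min_support=1)
        assert {(c.strand, c.n_support) for c in clusters} == {("+", 3), ("-", 2)}

    def test_matches_bruteforce_transitive_closure(self, rng):
        positions = sorted(int(p) for p in rng.integers(0, 20_000, 50))
        pers = [per_at(p) for p in positions]
        clusters = cluster_pers(pers, LIB, min_support=1)
        got = sorted(tuple(sorted(m.anchor_pos for m in c.members)) for c in clusters)
        # brute force: transitive closure of the pairwise <= window relation
        window = LIB.cluster_window
        parent = list(range(len(positions)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(positions)), 2):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
        groups = {}
        for i, p in enumerate(positions):
            groups.setdefault(find(i), []).append(p)
        expected = sorted(tuple(sorted(g)) for g in groups.values())
        assert got == expected

    def test_order_invariance(self, rng):
        positions = [int(p) for p in rng.integers(0, 50_000, 40)]
        pers = [per_at(p) for p in positions]
        a = cluster_pers(pers, LIB, min_support=2)
        shuffled = list(pers)
        rng.shuffle(shuffled)
        b = cluster_pers(shuffled, LIB, min_support=2)
        assert [(c.start, c.end, c.n_support) for c in a] == [
            (c.start, c.end, c.n_support) for c in b
        ]


class TestRefineBreakpoint:
    def test_left_flank_split(self, rng):
        ref = random_dna(3000, rng)
        contig = ref[1000:1100] + "GATTACA" * 5
        tag = refine_breakpoint(contig, ref, 0)
        assert (tag.breakpoint, tag.side) == (1100, LEFT)
        assert tag.flank_seq == ref[1000:1100]
        assert tag.ins_part_seq == "GATTACA" * 5

    def test_right_flank_split(self, rng):
        ref = random_dna(3000, rng)
        novel = random_dna(40, np.random.default_rng(4242))
        # guard the constructed case against chance microhomology at the join
        assert novel[-1] != ref[1999]
        contig = novel + ref[2000:2120]
        tag = refine_breakpoint(contig, ref, 0)
        assert (tag.breakpoint, tag.side) == (2000, RIGHT)
        assert tag.ins_part_seq == novel

    def test_mismatches_in_flank_keep_breakpoint(self, rng):
        ref = random_dna(3000, rng)
        flank = list(ref[800:1100])
        flank[50] = _flip(flank[50])
        flank[200] = _flip(flank[200])
        ins = random_dna(60, np.random.default_rng(77))
        assert ins[0] != ref[1100]
        tag = refine_breakpoint("".join(flank) + ins, ref, 0, tol=0.01)
        exact = refine_breakpoint(ref[800:1100] + ins, ref, 0, tol=0.01)
        assert tag.breakpoint == exact.breakpoint == 1100
        # exhaustive-scan oracle over all split points at the known offset
        contig = "".join(flank) + ins
        best = max(
            (i for i in range(15, len(contig) + 1)
             if sum(a != b for a, b in zip(contig[:i], ref[800:800 + i])) <= 0.01 * i),
            key=lambda i: (i - 5 * sum(a != b for a, b in zip(contig[:i], ref[800:800 + i])), i),
        )
        assert 800 + best == tag.breakpoint

    def test_fully_reference_contig_yields_none(self, rng):
        ref = random_dna(3000, rng)
        assert refine_breakpoint(ref[500:900], ref, 0) is None

    def test_short_flank_or_ins_part_rejected(self, rng):
        ref = random_dna(3000, rng)
        assert refine_breakpoint(ref[1090:1100] + "GATTACA" * 10, ref, 0) is None
        assert refine_breakpoint(ref[1000:1100] + "GATTA", ref, 0) is None


def _flip(b: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


class TestValidateContig:
    def _cluster(self, reads):
        pers = []
        for i, (rid, seq) in enumerate(reads):
            pers.append(DiscordantPER(
                anchor_chrom="chr1", anchor_pos=100 + i, anchor_strand="+",
                anchor_cigar="", anchor_mapq=60, anchor_seq=seq, mate_seq="",
                mate_status="unmapped", qname=rid.rsplit("/", 1)[0],
            ))
        from insertag.discovery import PERCluster

        return PERCluster("chr1", "+", 100, 100 + len(reads), pers)

    def test_contiguous_same_strand_accepted(self):
        contig = Contig(seq="A" * 300, k=21,
                        read_placements=[(f"q{i}/a", i * 40, "+") for i in range(6)])
        cluster = self._cluster([(f"q{i}/a", "A" * 100) for i in range(6)])
        assert validate_contig(contig, cluster, 100)

    def test_gap_between_islands_rejected(self):
        contig = Contig(seq="A" * 900, k=21,
                        read_placements=[("q0/a", 0, "+"), ("q1/a", 700, "+")])
        cluster = self._cluster([("q0/a", "A" * 100), ("q1/a", "A" * 100)])
        assert not validate_contig(contig, cluster, 100)

    def test_wrong_strand_rejected(self):
        contig = Contig(seq="A" * 200, k=21,
                        read_placements=[("q0/a", 0, "+"), ("q1/a", 50, "-")])
        cluster = self._cluster([("q0/a", "A" * 100), ("q1/a", "A" * 100)])
        assert not validate_contig(contig, cluster, 100)

    def test_random_sets_match_bruteforce_chain_check(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            offs = sorted(int(o) for o in rng.integers(0, 600, n))
            contig = Contig(seq="A" * 800, k=21,
                            read_placements=[(f"q{i}/a", o, "+") for i, o in enumerate(offs)])
            cluster = self._cluster([(f"q{i}/a", "A" * 100) for i in range(n)])
            expected = all(
                offs[i + 1] - (offs[i] + 100) <= 100 for i in range(n - 1)
            )
            # brute-force re-check of the chain condition with interval union
            assert validate_contig(contig, cluster, 100) == expected


def tag(bp: int, side: str, chrom="chr1") -> InsertionTag:
    return InsertionTag(chrom=chrom, breakpoint=bp, side=side,
                        flank_seq="A" * 40, ins_part_seq="C" * 30)


class TestPairing:
    def test_nearby_pair_forms(self):
        pairs = pair_insertion_tags([tag(1100, LEFT), tag(1105, RIGHT)], LIB)
        assert len(pairs) == 1
        assert pairs[0].site == (1100, 1105)

    def test_window_exceeded_no_pair(self):
        assert pair_insertion_tags([tag(1100, LEFT), tag(9000, RIGHT)], LIB) == []

    def test_large_negative_gap_rejected(self):
        # reciprocal tags of a donor-locus artifact: right far upstream of left
        assert pair_insertion_tags([tag(5000, LEFT), tag(4000, RIGHT)], LIB) == []

    def test_matches_bruteforce_min_gap_matching(self, rng):
        for trial in range(20):
            tags = []
            for i in range(20):
                side = LEFT if rng.random() < 0.5 else RIGHT
                tags.append(tag(int(rng.integers(0, 3000)), side))
            got = pair_insertion_tags(
                tags, LIB, microhomology_slack=20, max_pair_gap=100
            )
            got_pairs = sorted((p.left.breakpoint, p.right.breakpoint) for p in got)
            expected = brute_force_pairing(tags, min(LIB.cluster_window, 100), 20)
            assert got_pairs == expected


def brute_force_pairing(tags, window, slack):
    lefts = [(i, t) for i, t in enumerate(tags) if t.side == LEFT]
    rights = [(i, t) for i, t in enumerate(tags) if t.side == RIGHT]
    cand = []
    for li, (i, lt) in enumerate(lefts):
        for rj, (j, rt) in enumerate(rights):
            gap = rt.breakpoint - lt.breakpoint
            if -slack <= gap <= window:
                cand.append((abs(gap), lt.breakpoint, li, rj))
    cand.sort()
    used_l, used_r, out = set(), set(), []
    for _, _, li, rj in cand:
        if li in used_l or rj in used_r:
            continue
        used_l.add(li)
        used_r.add(rj)
        out.append((lefts[li][1].breakpoint, rights[rj][1].breakpoint))
    return sorted(out)
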