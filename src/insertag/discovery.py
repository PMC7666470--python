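"""Discovery of insertion-tags from clustered discordant PERs.

Anchored reads are clustered per (chromosome, strand) by single linkage with
a link distance of mean insert + 2 sd. Each cluster is assembled into local
contigs from anchored and overhang sequences simultaneously; the accepted
contig is split against the local reference into a flanking reference part
and a partial inserted part at the phase-changing point (the breakpoint).
A left-flank tag (from '+' anchors) and a right-flank tag (from '-' anchors)
within the insert-size window are paired into one putative insertion event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from pyfaidx import Fasta

from . import assembly
from .io_alignments import DiscordantPER, LibraryStats, extract_discordant_pers, estimate_library_stats

log = logging.getLogger(__name__)

LEFT, RIGHT = "left_flank", "right_flank"


@dataclass
class PERCluster:
    chrom: str
    strand: str
    start: int
    end: int  # half-open span of anchored-read start positions
    members: list[DiscordantPER]

    @property
    def n_support(self) -> int:
        return len(self.members)


@dataclass
class InsertionTag:
    chrom: str
    breakpoint: int  # 0-based reference coordinate of the phase change
    side: str  # LEFT | RIGHT
    flank_seq: str
    ins_part_seq: str
    source_cluster: int = -1
    n_support: int = 0


@dataclass
class PairedInsertionTag:
    left: InsertionTag
    right: InsertionTag

    @property
    def chrom(self) -> str:
        return self.left.chrom

    @property
    def site(self) -> tuple[int, int]:
        return (self.left.breakpoint, self.right.breakpoint)

    @property
    def breakpoint(self) -> int:
        return self.left.breakpoint


def cluster_pers(
    pers: list[DiscordantPER], lib: LibraryStats, min_support: int = 3
) -> list[PERCluster]:
    """Single-linkage clustering of anchors by (chrom, strand) and position."""
    window = lib.cluster_window
    ordered = sorted(pers, key=lambda p: (p.anchor_chrom, p.anchor_strand, p.anchor_pos))
    clusters: list[PERCluster] = []
    cur: list[DiscordantPER] = []

    def flush() -> None:
        if len(cur) >= min_support:
            clusters.append(
                PERCluster(
                    chrom=cur[0].anchor_chrom,
                    strand=cur[0].anchor_strand,
                    start=cur[0].anchor_pos,
                    end=cur[-1].anchor_pos + 1,
                    members=list(cur),
                )
            )

    for per in ordered:
        if cur and (
            per.anchor_chrom != cur[-1].anchor_chrom
            or per.anchor_strand != cur[-1].anchor_strand
            or per.anchor_pos - cur[-1].anchor_pos > window
        ):
            flush()
            cur = []
        cur.append(per)
    if cur:
        flush()
    return clusters


def assemble_cluster(
    cluster: PERCluster,
    k: int = 31,
    max_reads: int = 600,
    min_kmer_count: int = 1,
    prune_ratio: float = 0.2,
) -> list[assembly.Contig]:
    """Assemble anchored and overhang sequences of one cluster, one strand.

    Mate sequences were oriented genome-forward at extraction time, so the
    whole read set is assembled in a single orientation. Oversized clusters
    (typically repeat-driven) are truncated deterministically.
    """
    reads: list[tuple[str, str]] = []
    for i, per in enumerate(cluster.members[:max_reads]):
        if per.anchor_seq:
            reads.append((f"{per.qname}/a", per.anchor_seq))
        if per.mate_seq:
            reads.append((f"{per.qname}/m", per.mate_seq))
    return assembly.assemble(
        reads, k=k, min_kmer_count=min_kmer_count, prune_ratio=prune_ratio
    )


def validate_contig(
    contig: assembly.Contig, cluster: PERCluster, read_length: int
) -> bool:
    """Accept a contig iff its read placements form one strand-consistent chain.

    All placed reads must match the assembly orientation ('+', since members
    were pre-oriented) and consecutive placements must not leave an unsupported
    gap larger than the read length (guards against chimeric joins).
    """
    placements = contig.read_placements
    if not placements:
        return False
    if any(strand != "+" for _, _, strand in placements):
        return False
    lens = {rid: len(seq) for rid, seq in _cluster_reads(cluster)}
    ordered = sorted(placements, key=lambda p: p[1])
    max_end = None
    for rid, off, _ in ordered:
        rlen = lens.get(rid, read_length)
        if max_end is not None and off - max_end > read_length:
            return False
        end = off + rlen
        max_end = end if max_end is None else max(max_end, end)
    return True


def _cluster_reads(cluster: PERCluster):
    for per in cluster.members:
        if per.anchor_seq:
            yield (f"{per.qname}/a", per.anchor_seq)
        if per.mate_seq:
            yield (f"{per.qname}/m", per.mate_seq)


def _best_prefix_split(
    contig: np.ndarray, ref: np.ndarray, tol: float, seed_len: int = 12
) -> tuple[int, int] | None:
    """Longest contig prefix matching the reference at some offset.

    Seeds candidate offsets with exact ``seed_len``-mers from the contig start,
    then for each offset does an exhaustive scan over split points, choosing
    the largest split i whose prefix mismatch fraction is <= tol and whose
    final base matches. Returns (ref_offset, flank_len) or None.
    """
    n, m = len(contig), len(ref)
    if n < seed_len or m < seed_len:
        return None
    best: tuple[int, int] | None = None
    ref_bytes = ref.tobytes()
    seen_offsets: set[int] = set()
    for anchor in (0, seed_len // 2, seed_len):
        if anchor + seed_len > n:
            break
        seed = contig[anchor : anchor + seed_len].tobytes()
        start = 0
        while True:
            j = ref_bytes.find(seed, start)
            if j < 0:
                break
            start = j + 1
            off = j - anchor
            if off < 0 or off in seen_offsets:
                continue
            seen_offsets.add(off)
            span = min(n, m - off)
            if span <= 0:
                continue
            mism = np.cumsum(contig[:span] != ref[off : off + span])
            idx = np.arange(1, span + 1)
            ok = (mism <= tol * idx) & (contig[:span] == ref[off : off + span])
            hits = np.nonzero(ok)[0]
            if hits.size == 0:
                continue
            # Score each admissible split as matches minus 4x mismatches so a
            # residual mismatch budget cannot drag the flank past the true
            # junction into the inserted sequence; ties go to the longer flank.
            lens = hits + 1
            scores = lens - 5 * mism[hits]
            top = int(np.max(scores))
            flank = int(lens[scores == top].max())
            if best is None or flank > best[1]:
                best = (off, flank)
    return best


def refine_breakpoint(
    contig: assembly.Contig | str,
    local_ref: str,
    origin: int,
    chrom: str = "",
    side_hint: str | None = None,
    min_flank: int = 15,
    min_ins_part: int = 10,
    tol: float = 0.02,
) -> InsertionTag | None:
    """Split a contig into flank and inserted parts at the phase change.

    The split point maximizing flank identity is chosen (ties toward the
    longer flank). ``side_hint`` restricts the search to one interpretation
    (left-flank: contig prefix matches the reference; right-flank: suffix).
    Returns None when no reference-matching segment of at least ``min_flank``
    bp or no clipped remainder of at least ``min_ins_part`` bp exists.
    """
    seq = contig.seq if isinstance(contig, assembly.Contig) else contig
    c = np.frombuffer(seq.encode(), dtype=np.uint8)
    r = np.frombuffer(local_ref.encode(), dtype=np.uint8)
    candidates: list[InsertionTag] = []
    if side_hint in (None, LEFT):
        hit = _best_prefix_split(c, r, tol)
        if hit is not None:
            off, flank = hit
            if flank >= min_flank and len(seq) - flank >= min_ins_part:
                candidates.append(
                    InsertionTag(
                        chrom=chrom,
                        breakpoint=origin + off + flank,
                        side=LEFT,
                        flank_seq=seq[:flank],
                        ins_part_seq=seq[flank:],
                    )
                )
    if side_hint in (None, RIGHT):
        hit = _best_prefix_split(c[::-1].copy(), r[::-1].copy(), tol)
        if hit is not None:
            off, flank = hit
            if flank >= min_flank and len(seq) - flank >= min_ins_part:
                candidates.append(
                    InsertionTag(
                        chrom=chrom,
                        breakpoint=origin + len(local_ref) - off - flank,
                        side=RIGHT,
                        flank_seq=seq[len(seq) - flank :],
                        ins_part_seq=seq[: len(seq) - flank],
                    )
                )
    if not candidates:
        return None
    return max(candidates, key=lambda t: len(t.flank_seq))


def pair_insertion_tags(
    tags: list[InsertionTag],
    lib: LibraryStats,
    microhomology_slack: int = 20,
    max_pair_gap: int = 100,
) -> list[PairedInsertionTag]:
    """Pair left- and right-flank tags within the insert-size window.

    Greedy one-to-one matching by ascending absolute breakpoint gap. Tags are
    scanned against each other within the insert-size window (mean + 2 sd),
    but a pair is only accepted when its breakpoints agree: the gap (right
    breakpoint minus left breakpoint) must lie within
    [-microhomology_slack, max_pair_gap], since the two tags of one insertion
    event describe the same junction and repeat-driven artifact tags at
    nearby distinct loci should not couple.
    """
    window = min(lib.cluster_window, max_pair_gap)
    lefts = [t for t in tags if t.side == LEFT]
    rights = [t for t in tags if t.side == RIGHT]
    cand: list[tuple[int, int, int, int]] = []
    for i, lt in enumerate(lefts):
        for j, rt in enumerate(rights):
            if lt.chrom != rt.chrom:
                continue
            gap = rt.breakpoint - lt.breakpoint
            if -microhomology_slack <= gap <= window:
                cand.append((abs(gap), lt.breakpoint, i, j))
    cand.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs: list[PairedInsertionTag] = []
    for _, _, i, j in cand:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        pairs.append(PairedInsertionTag(left=lefts[i], right=rights[j]))
    pairs.sort(key=lambda p: (p.chrom, p.breakpoint))
    return pairs


@dataclass
class DiscoveryStats:
    n_pers: int = 0
    n_clusters: int = 0
    n_contigs_accepted: int = 0
    n_contigs_rejected: int = 0
    n_tags: int = 0
    n_pairs: int = 0


def discover(
    bam_path: str,
    reference_path: str,
    min_mapq: int = 20,
    min_support: int = 3,
    k: int = 31,
    min_flank: int = 15,
    min_ins_part: int = 10,
    tol: float = 0.02,
    microhomology_slack: int = 20,
    max_pair_gap: int = 100,
    lib: LibraryStats | None = None,
) -> tuple[list[PairedInsertionTag], list[InsertionTag], DiscoveryStats]:
    """Full discovery stage: BAM -> paired insertion-tags.

    Per cluster, only the highest-read-support contig is carried forward;
    alternates are counted but dropped.
    """
    stats = DiscoveryStats()
    if lib is None:
        lib = estimate_library_stats(bam_path)
    pers = list(extract_discordant_pers(bam_path, min_mapq=min_mapq, lib=lib))
    stats.n_pers = len(pers)
    clusters = cluster_pers(pers, lib, min_support=min_support)
    stats.n_clusters = len(clusters)
    ref = Fasta(reference_path, as_raw=True, sequence_always_upper=True)
    pad = lib.cluster_window + lib.read_length
    tags: list[InsertionTag] = []
    for ci, cluster in enumerate(clusters):
        contigs = assemble_cluster(cluster, k=k)
        origin = max(0, cluster.start - pad)
        end = min(len(ref[cluster.chrom]), cluster.end + pad)
        local_ref = str(ref[cluster.chrom][origin:end])
        # The best-supported contig is often pure flank when assembly breaks
        # at the junction; take the best-supported contig that actually
        # carries breakpoint evidence. Both split interpretations are tried:
        # a '+' cluster normally yields a left-flank tag, but when the
        # insertion is shorter than the insert size its overhang reads can
        # reach across into the right flank instead.
        tag = None
        n_valid = 0
        for contig in contigs:
            if not validate_contig(contig, cluster, lib.read_length):
                continue
            n_valid += 1
            tag = refine_breakpoint(
                contig,
                local_ref,
                origin,
                chrom=cluster.chrom,
                side_hint=None,
                min_flank=min_flank,
                min_ins_part=min_ins_part,
                tol=tol,
            )
            if tag is not None:
                break
        stats.n_contigs_accepted += n_valid
        stats.n_contigs_rejected += len(contigs) - n_valid
        if tag is not None:
            tag.source_cluster = ci
            tag.n_support = cluster.n_support
            tags.append(tag)
    stats.n_tags = len(tags)
    pairs = pair_insertion_tags(
        tags, lib, microhomology_slack=microhomology_slack, max_pair_gap=max_pair_gap
    )
    stats.n_pairs = len(pairs)
    log.info(
        "discovery: %d PERs -> %d clusters -> %d tags -> %d pairs",
        stats.n_pers, stats.n_clusters, stats.n_tags, stats.n_pairs,
    )
    return pairs, tags, stats
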