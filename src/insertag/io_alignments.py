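"""Alignment input: library statistics and discordant paired-end read selection.

The atomic unit of evidence for insertion discovery is the discordant PER: a
read pair in which one end ("anchor") maps confidently to the reference and
the other end ("overhang") is unmapped or maps discordantly. Concordant,
properly paired fragments carry no insertion signal at this layer and are
discarded as early as possible so that a single streaming pass over a
coordinate-sorted BAM stays cheap.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pysam

from ._seq import revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryStats:
    """Outer insert length distribution and modal read length of a library."""

    mean_insert: float
    sd_insert: float
    read_length: int

    def __post_init__(self) -> None:
        if self.mean_insert <= 0 or self.sd_insert < 0 or self.read_length <= 0:
            raise ValueError(f"invalid library stats: {self}")

    @property
    def cluster_window(self) -> int:
        """Linkage / pairing window: mean insert plus two standard deviations."""
        return int(round(self.mean_insert + 2 * self.sd_insert))

    @property
    def discordance_window(self) -> int:
        """Insert-size anomaly bound: mean insert plus three standard deviations."""
        return int(round(self.mean_insert + 3 * self.sd_insert))


@dataclass(frozen=True)
class DiscordantPER:
    """One read pair with an anchored end and an unmapped/discordant mate.

    ``mate_seq`` is stored already oriented into the anchor's genome-forward
    frame (for an FR library the overhang of a forward anchor is sequenced
    from the reverse strand), so downstream assembly is strand-free.
    """

    anchor_chrom: str
    anchor_pos: int
    anchor_strand: str
    anchor_cigar: str
    anchor_mapq: int
    anchor_seq: str
    mate_seq: str
    mate_status: str  # "unmapped" | "discordant"
    qname: str


def _records(alignments) -> tuple[Iterator[pysam.AlignedSegment], pysam.AlignmentFile | None]:
    if isinstance(alignments, (str,)):
        fh = pysam.AlignmentFile(alignments, check_sq=False)
        return fh.fetch(until_eof=True), fh
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments.fetch(until_eof=True), None
    return iter(alignments), None


def _usable(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_secondary or rec.is_supplementary or rec.is_duplicate or rec.is_qcfail
    )


def estimate_library_stats(
    alignments, sample_size: int = 100_000, min_proper_pairs: int = 50
) -> LibraryStats:
    """Estimate insert mean/sd and modal read length from properly paired reads.

    Only primary, non-duplicate, properly paired records with positive TLEN
    contribute (each pair counted once). Raises ``ValueError`` naming the
    observed count when fewer than ``min_proper_pairs`` proper pairs exist.
    """
    stream, fh = _records(alignments)
    inserts: list[int] = []
    read_lengths: Counter[int] = Counter()
    try:
        for rec in stream:
            if not _usable(rec):
                continue
            if rec.query_length:
                read_lengths[rec.query_length] += 1
            if rec.is_proper_pair and not rec.is_unmapped and rec.template_length > 0:
                inserts.append(rec.template_length)
                if len(inserts) >= sample_size:
                    break
    finally:
        if fh is not None:
            fh.close()
    if len(inserts) < min_proper_pairs:
        raise ValueError(
            f"cannot estimate library stats: {len(inserts)} proper pairs found "
            f"(minimum {min_proper_pairs})"
        )
    arr = np.asarray(inserts, dtype=float)
    read_length = read_lengths.most_common(1)[0][0]
    return LibraryStats(float(arr.mean()), float(arr.std()), int(read_length))


def pair_is_discordant(
    rec: pysam.AlignedSegment, lib: LibraryStats | None = None
) -> bool:
    """Discordance predicate for a both-ends-mapped pair, from one record.

    A pair is discordant when the mates are on different chromosomes, in
    non-FR orientation, or the outer insert exceeds mean + 3 sd (when library
    stats are available). Decidable from a single record's mate fields.
    """
    if rec.reference_id != rec.next_reference_id:
        return True
    if rec.is_reverse == rec.mate_is_reverse:
        return True
    # FR orientation: the forward-strand read must be leftmost.
    fwd_pos = rec.next_reference_start if rec.is_reverse else rec.reference_start
    rev_pos = rec.reference_start if rec.is_reverse else rec.next_reference_start
    if fwd_pos > rev_pos:
        return True
    if lib is not None and abs(rec.template_length) > lib.discordance_window:
        return True
    return False


def _as_sequenced(rec: pysam.AlignedSegment) -> str:
    seq = rec.query_sequence or ""
    return revcomp(seq) if rec.is_reverse else seq


def _orient_mate(mate_as_sequenced: str, anchor_strand: str) -> str:
    # FR library: the overhang of a '+' anchor was sequenced from the reverse
    # strand of the fragment, so its genome-forward sequence is the revcomp.
    return revcomp(mate_as_sequenced) if anchor_strand == "+" else mate_as_sequenced


def extract_discordant_pers(
    alignments, min_mapq: int = 20, lib: LibraryStats | None = None
) -> Iterator[DiscordantPER]:
    """Stream discordant PERs from an alignment file or record iterable.

    Emits one record per qualifying (anchor, overhang) combination: pairs with
    an unmapped end yield at most one (the mapped end anchors), both-mapped
    discordant pairs yield one per sufficiently high-MAPQ end. Anchors below
    ``min_mapq`` are excluded. Secondary/supplementary/duplicate records are
    ignored; an unmapped mate without sequence is skipped with a warning.
    """
    stream, fh = _records(alignments)
    pending: dict[str, pysam.AlignedSegment] = {}
    n_orphan = 0
    try:
        for rec in stream:
            if not _usable(rec) or not rec.is_paired:
                continue
            if rec.is_unmapped and rec.mate_is_unmapped:
                continue
            if (
                not rec.is_unmapped
                and not rec.mate_is_unmapped
                and not pair_is_discordant(rec, lib)
            ):
                continue  # concordant pair: decidable without the partner
            other = pending.pop(rec.qname, None)
            if other is None:
                pending[rec.qname] = rec
                continue
            yield from _emit_pair(rec, other, min_mapq)
        n_orphan = len(pending)
    finally:
        if fh is not None:
            fh.close()
    if n_orphan:
        log.warning("%d discordant candidates had no usable mate record", n_orphan)


def _emit_pair(
    a: pysam.AlignedSegment, b: pysam.AlignedSegment, min_mapq: int
) -> Iterator[DiscordantPER]:
    for anchor, mate in ((a, b), (b, a)):
        if anchor.is_unmapped or anchor.mapping_quality < min_mapq:
            continue
        status = "unmapped" if mate.is_unmapped else "discordant"
        mate_seq = _as_sequenced(mate)
        if not mate_seq:
            log.warning("missing mate sequence for pair %s; skipped", anchor.qname)
            continue
        strand = "-" if anchor.is_reverse else "+"
        yield DiscordantPER(
            anchor_chrom=anchor.reference_name,
            anchor_pos=anchor.reference_start,
            anchor_strand=strand,
            anchor_cigar=anchor.cigarstring or "",
            anchor_mapq=anchor.mapping_quality,
            anchor_seq=anchor.query_sequence or "",
            mate_seq=_orient_mate(mate_seq, strand),
            mate_status=status,
            qname=anchor.qname,
        )
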