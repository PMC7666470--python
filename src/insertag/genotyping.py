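"""Read-depth-ratio genotyping of sequence-resolved insertion variants.

For each catalogued variant two local alleles are built: the reference
allele spanning the breakpoint and the insertion allele with the full
inserted sequence spliced in. Raw reads fetched around the breakpoint are
aligned to both alleles; a read supports an allele only when its alignment
is strictly better by a score margin and crosses a breakpoint junction by at
least ``min_overlap`` bp. The biallelic genotype is then a simple function
of the supporting read-depth ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import pysam
from pyfaidx import Fasta

from ._seq import revcomp

log = logging.getLogger(__name__)

REF, ALT, AMBIGUOUS = "ref", "alt", "ambiguous"


@dataclass(frozen=True)
class AllelePair:
    variant_id: str
    ref_allele_seq: str
    ins_allele_seq: str
    breakpoint_offset: int  # junction position within both alleles
    ins_len: int

    @property
    def ref_junctions(self) -> tuple[int, ...]:
        return (self.breakpoint_offset,)

    @property
    def ins_junctions(self) -> tuple[int, ...]:
        return (self.breakpoint_offset, self.breakpoint_offset + self.ins_len)


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    variant_id: str
    n_ref: int
    n_alt: int
    gt: str  # 0/0 | 0/1 | 1/1 | ./.
    alt_ratio: float | None


def build_alleles(
    chrom: str,
    breakpoint: int,
    ins_seq: str,
    reference: Fasta,
    flank_extension: int,
    variant_id: str = "",
) -> AllelePair:
    """Construct the reference and insertion alleles around one breakpoint.

    ``flank_extension`` should be at least the read length so that reads can
    span a junction entirely within one allele.
    """
    if not ins_seq:
        raise ValueError(f"variant {variant_id or chrom}: empty insertion sequence")
    clen = len(reference[chrom])
    if breakpoint - flank_extension < 0 or breakpoint + flank_extension > clen:
        raise ValueError(
            f"variant {variant_id or chrom}:{breakpoint} within {flank_extension} bp "
            "of a contig end"
        )
    left = str(reference[chrom][breakpoint - flank_extension : breakpoint])
    right = str(reference[chrom][breakpoint : breakpoint + flank_extension])
    return AllelePair(
        variant_id=variant_id or f"{chrom}:{breakpoint}",
        ref_allele_seq=left + right,
        ins_allele_seq=left + ins_seq + right,
        breakpoint_offset=len(left),
        ins_len=len(ins_seq),
    )


def _best_alignment(read: str, allele: str, max_dist: int):
    best = (max_dist + 1, None)
    for seq in (read, revcomp(read)):
        res = edlib.align(seq, allele, mode="HW", task="locations", k=max_dist)
        d = res["editDistance"]
        if d >= 0 and d < best[0]:
            best = (d, res["locations"][0])
    return best


def _spans_junction(loc: tuple[int, int], junctions: tuple[int, ...], min_overlap: int) -> bool:
    start, end = loc[0], loc[1] + 1  # edlib locations are inclusive
    return any(
        start <= j - min_overlap and end >= j + min_overlap for j in junctions
    )


def assign_read(
    read: str,
    pair: AllelePair,
    score_margin: int = 3,
    min_overlap: int = 10,
    max_dist_frac: float = 0.25,
) -> str:
    """Assign a read to the better-matching allele, or call it ambiguous.

    Both orientations are aligned end-free inside each allele; the read is
    assigned only when one allele is better by at least ``score_margin`` edit
    units and the winning alignment crosses a breakpoint junction.
    """
    max_dist = max(2, int(max_dist_frac * len(read)))
    d_ref, loc_ref = _best_alignment(read, pair.ref_allele_seq, max_dist)
    d_alt, loc_alt = _best_alignment(read, pair.ins_allele_seq, max_dist)
    if d_alt + score_margin <= d_ref and loc_alt is not None:
        if _spans_junction(loc_alt, pair.ins_junctions, min_overlap):
            return ALT
    elif d_ref + score_margin <= d_alt and loc_ref is not None:
        if _spans_junction(loc_ref, pair.ref_junctions, min_overlap):
            return REF
    return AMBIGUOUS


def call_genotype(
    n_ref: int,
    n_alt: int,
    thresholds: tuple[float, float] = (0.2, 0.8),
    min_depth: int = 4,
    sample: str = "",
    variant_id: str = "",
) -> GenotypeCall:
    """Biallelic genotype from the supporting read-depth ratio."""
    t_low, t_high = thresholds
    depth = n_ref + n_alt
    if depth < min_depth:
        return GenotypeCall(sample, variant_id, n_ref, n_alt, "./.", None)
    ratio = n_alt / depth
    if ratio <= t_low:
        gt = "0/0"
    elif ratio >= t_high:
        gt = "1/1"
    else:
        gt = "0/1"
    return GenotypeCall(sample, variant_id, n_ref, n_alt, gt, ratio)


def genotype_reads(
    reads: list[str],
    pair: AllelePair,
    thresholds: tuple[float, float] = (0.2, 0.8),
    min_depth: int = 4,
    score_margin: int = 3,
    min_overlap: int = 10,
    sample: str = "",
) -> GenotypeCall:
    """Genotype one variant from an explicit read set (ambiguous reads dropped)."""
    n_ref = n_alt = 0
    for read in reads:
        verdict = assign_read(read, pair, score_margin=score_margin, min_overlap=min_overlap)
        if verdict == REF:
            n_ref += 1
        elif verdict == ALT:
            n_alt += 1
    return call_genotype(
        n_ref, n_alt, thresholds, min_depth, sample=sample, variant_id=pair.variant_id
    )


def genotype_sample(
    variants: list[tuple[str, str, int, str]],
    bam_path: str,
    reference_path: str,
    read_length: int = 100,
    flank_extension: int | None = None,
    thresholds: tuple[float, float] = (0.2, 0.8),
    min_depth: int = 4,
    score_margin: int = 3,
    min_overlap: int = 10,
    sample: str = "",
) -> tuple[list[GenotypeCall], list[tuple[str, str]]]:
    """Genotype a catalogue in one sample BAM.

    ``variants`` holds (variant_id, chrom, breakpoint, full_ins_seq) tuples.
    Variants whose length does not exceed max(read_length, 100) are skipped
    with a reason (mutations near breakpoints make shorter variants unsafe to
    type by alignment-score comparison). Returns (calls, skipped).
    """
    fe = flank_extension if flank_extension is not None else read_length + 50
    ref = Fasta(reference_path, as_raw=True, sequence_always_upper=True)
    min_len = max(read_length, 100)
    calls: list[GenotypeCall] = []
    skipped: list[tuple[str, str]] = []
    with pysam.AlignmentFile(bam_path) as bam:
        for vid, chrom, bp, ins_seq in variants:
            if len(ins_seq) <= min_len:
                skipped.append((vid, f"SVLEN {len(ins_seq)} <= {min_len}"))
                continue
            try:
                pair = build_alleles(chrom, bp, ins_seq, ref, fe, variant_id=vid)
            except ValueError as exc:
                skipped.append((vid, str(exc)))
                continue
            start = max(0, bp - fe)
            end = min(len(ref[chrom]), bp + fe)
            reads = []
            seen: set[tuple[str, bool]] = set()
            for rec in bam.fetch(chrom, start, end):
                if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                    continue
                key = (rec.query_name, rec.is_read1)
                if key in seen or not rec.query_sequence:
                    continue
                seen.add(key)
                reads.append(rec.query_sequence)
            calls.append(
                genotype_reads(
                    reads, pair, thresholds, min_depth,
                    score_margin=score_margin, min_overlap=min_overlap, sample=sample,
                )
            )
    return calls, skipped
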