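import numpy as np
import pysam
import pytest

from insertag._seq import revcomp

BASES = "ACGT"


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": "chr1", "LN": 1_000_000},
                {"SN": "chr2", "LN": 1_000_000},
            ],
        }
    )


def make_read(
    header,
    qname: str,
    chrom: str | None,
    pos: int,
    seq: str,
    is_read1: bool = True,
    reverse: bool = False,
    mapq: int = 60,
    mate_chrom: str | None = None,
    mate_pos: int = -1,
    mate_reverse: bool = False,
    mate_unmapped: bool = False,
    unmapped: bool = False,
    proper: bool = False,
    tlen: int = 0,
    cigar: str | None = None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    a.is_paired = True
    a.is_read1 = is_read1
    a.is_read2 = not is_read1
    a.is_unmapped = unmapped
    a.is_reverse = reverse
    a.mate_is_unmapped = mate_unmapped
    a.mate_is_reverse = mate_reverse
    a.is_proper_pair = proper
    a.mapping_quality = 0 if unmapped else mapq
    if chrom is not None:
        a.reference_id = header.get_tid(chrom)
        a.reference_start = pos
    if not unmapped:
        a.cigarstring = cigar or f"{len(seq)}M"
    if mate_chrom is not None:
        a.next_reference_id = header.get_tid(mate_chrom)
        a.next_reference_start = mate_pos
    a.template_length = tlen
    return a


def make_proper_pair(header, qname, chrom, pos, insert, read_len=100, rng=None):
    """A concordant FR pair with the given outer insert length."""
    seq1 = "A" * read_len if rng is None else random_dna(read_len, rng)
    seq2 = "C" * read_len if rng is None else random_dna(read_len, rng)
    r1 = make_read(
        header, qname, chrom, pos, seq1, is_read1=True, mate_chrom=chrom,
        mate_pos=pos + insert - read_len, mate_reverse=True, proper=True, tlen=insert,
    )
    r2 = make_read(
        header, qname, chrom, pos + insert - read_len, seq2, is_read1=False,
        reverse=True, mate_chrom=chrom, mate_pos=pos, proper=True, tlen=-insert,
    )
    return [r1, r2]


def write_bam(path: str, header, records) -> str:
    ordered = sorted(
        records, key=lambda r: (r.reference_id if r.reference_id >= 0 else 1 << 30,
                                r.reference_start if r.reference_start >= 0 else 1 << 30)
    )
    with pysam.AlignmentFile(path, "wb", header=header) as fh:
        for rec in ordered:
            fh.write(rec)
    pysam.index(path)
    return path
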