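"""Thin adapters around standard command-line aligners (SAM in, SAM out).

The pipeline's own algorithmics never depend on a particular aligner; these
helpers only shell out to ``bwa``/``minimap2``/``samtools`` to produce the
coordinate-sorted BAMs and query hit tables the other modules consume.
"""

from __future__ import annotations

import logging
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass

import pysam

log = logging.getLogger(__name__)


def _run(cmd, **kw) -> None:
    log.debug("running: %s", " ".join(map(str, cmd)))
    subprocess.run(list(map(str, cmd)), check=True, **kw)


def require_tool(name: str) -> str:
    path = shutil.which(name)
    if path is None:
        raise RuntimeError(f"required external tool not found on PATH: {name}")
    return path


def combine_references(fasta_paths: list[str], out_fasta: str) -> str:
    """Concatenate reference FASTAs into one mapping reference and index it."""
    with open(out_fasta, "w") as out:
        for p in fasta_paths:
            with open(p) as fh:
                shutil.copyfileobj(fh, out)
    pysam.faidx(out_fasta)
    return out_fasta


def bwa_index(fasta: str) -> None:
    require_tool("bwa")
    _run(["bwa", "index", fasta], stderr=subprocess.DEVNULL)


def map_paired_reads(
    reference_fasta: str,
    fastq1: str,
    fastq2: str,
    out_bam: str,
    threads: int = 1,
    reindex: bool = True,
) -> str:
    """bwa mem paired-end mapping -> coordinate-sorted, indexed BAM."""
    require_tool("bwa")
    require_tool("samtools")
    if reindex or not os.path.exists(reference_fasta + ".bwt"):
        bwa_index(reference_fasta)
    with tempfile.TemporaryDirectory() as tmp:
        sam = os.path.join(tmp, "aln.sam")
        with open(sam, "w") as out:
            _run(
                ["bwa", "mem", "-t", threads, reference_fasta, fastq1, fastq2],
                stdout=out,
                stderr=subprocess.DEVNULL,
            )
        _run(["samtools", "sort", "-@", threads, "-o", out_bam, sam],
             stderr=subprocess.DEVNULL)
    _run(["samtools", "index", out_bam])
    return out_bam


@dataclass(frozen=True)
class QueryHit:
    query: str
    target: str
    start: int  # 0-based target interval of the alignment
    end: int
    strand: str
    mapq: int
    score: int
    query_start: int  # aligned query interval (soft clips excluded)
    query_end: int
    query_len: int


def map_queries(
    target_fasta: str,
    queries: dict[str, str],
    preset: str = "sr",
    primary_only: bool = True,
) -> dict[str, list[QueryHit]]:
    """Map named query sequences to a target FASTA with minimap2.

    Returns hits grouped by query name (primary alignments only by default).
    """
    require_tool("minimap2")
    hits: dict[str, list[QueryHit]] = {q: [] for q in queries}
    if not queries:
        return hits
    with tempfile.TemporaryDirectory() as tmp:
        qfa = os.path.join(tmp, "queries.fa")
        with open(qfa, "w") as fh:
            for name, seq in queries.items():
                fh.write(f">{name}\n{seq}\n")
        sam = os.path.join(tmp, "hits.sam")
        with open(sam, "w") as out:
            _run(
                ["minimap2", "-a", "-x", preset, "--secondary=no", target_fasta, qfa],
                stdout=out,
                stderr=subprocess.DEVNULL,
            )
        with pysam.AlignmentFile(sam, check_sq=False) as fh:
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                if primary_only and (rec.is_secondary or rec.is_supplementary):
                    continue
                qs, qe = _aligned_query_span(rec)
                hits[rec.query_name].append(
                    QueryHit(
                        query=rec.query_name,
                        target=rec.reference_name,
                        start=rec.reference_start,
                        end=rec.reference_end,
                        strand="-" if rec.is_reverse else "+",
                        mapq=rec.mapping_quality,
                        score=rec.get_tag("AS") if rec.has_tag("AS") else 0,
                        query_start=qs,
                        query_end=qe,
                        query_len=rec.infer_read_length() or len(queries[rec.query_name]),
                    )
                )
    return hits


def _aligned_query_span(rec: pysam.AlignedSegment) -> tuple[int, int]:
    """Aligned query interval in original (forward) query coordinates."""
    qs = rec.query_alignment_start
    qe = rec.query_alignment_end
    if rec.is_reverse:
        n = rec.infer_read_length()
        return n - qe, n - qs
    return qs, qe
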