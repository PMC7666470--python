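"""End-to-end simulation benchmark of the discovery stage.

Reproduces the validation protocol: implant donor segments into an acceptor
chromosome, simulate paired-end reads from the mutated acceptor, map them
against the acceptor alone ("unique" condition) or against acceptor plus
donor ("non-unique": reads from implanted segments can also map to their
donor locus), run discovery, and score paired insertion-tags against the
truth set with the gap < 100 bp / >= 50%-aligned matching rules.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from . import discovery, mapping, simulate

log = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    genome_length: int = 5_000_000
    gc: float = 0.41
    repeat_density: float = 0.2
    n_insertions: int = 100
    size_min: int = 100
    size_max: int = 20_000
    coverage: float = 30.0
    read_len: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    err: float = 0.002
    min_mapq: int = 20
    min_support: int = 3
    k: int = 31


@dataclass
class BenchmarkInputs:
    workdir: str
    acceptor_fa: str
    donor_fa: str
    truth: simulate.TruthSet
    fastq1: str
    fastq2: str
    config: BenchmarkConfig


def prepare_inputs(workdir: str, seed: int, config: BenchmarkConfig | None = None) -> BenchmarkInputs:
    """Generate genomes, implants, and reads once; mapping happens per condition."""
    cfg = config or BenchmarkConfig()
    os.makedirs(workdir, exist_ok=True)
    library = simulate.default_repeat_library()
    acceptor = simulate.generate_synthetic_genome(
        cfg.genome_length, cfg.gc, cfg.repeat_density, seed=seed, repeat_library=library
    )
    donor = simulate.generate_synthetic_genome(
        cfg.genome_length, cfg.gc, cfg.repeat_density, seed=seed + 1,
        repeat_library=library,
    )
    mutated, truth = simulate.implant_insertions(
        acceptor, donor, cfg.n_insertions, cfg.size_min, cfg.size_max, seed=seed + 2
    )
    acceptor_fa = simulate.write_fasta(
        os.path.join(workdir, "acceptor.fa"), {simulate.ACCEPTOR_NAME: acceptor}
    )
    donor_fa = simulate.write_fasta(
        os.path.join(workdir, "donor.fa"), {simulate.DONOR_NAME: donor}
    )
    truth.to_tsv(os.path.join(workdir, "truth.tsv"))
    fq1 = os.path.join(workdir, "reads_1.fq")
    fq2 = os.path.join(workdir, "reads_2.fq")
    n = simulate.simulate_pers(
        mutated, fq1, fq2,
        coverage=cfg.coverage, read_len=cfg.read_len,
        insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd,
        err=cfg.err, seed=seed + 3,
    )
    log.info("simulated %d read pairs over %d implants", n, len(truth))
    return BenchmarkInputs(workdir, acceptor_fa, donor_fa, truth, fq1, fq2, cfg)


def run_condition(inputs: BenchmarkInputs, unique: bool) -> simulate.EvalMetrics:
    """Map reads (acceptor only, or acceptor+donor), discover, and score."""
    cfg = inputs.config
    tag = "unique" if unique else "nonunique"
    ref_fa = os.path.join(inputs.workdir, f"mapref_{tag}.fa")
    sources = [inputs.acceptor_fa] if unique else [inputs.acceptor_fa, inputs.donor_fa]
    mapping.combine_references(sources, ref_fa)
    bam = os.path.join(inputs.workdir, f"aln_{tag}.bam")
    mapping.map_paired_reads(ref_fa, inputs.fastq1, inputs.fastq2, bam)
    pairs, _, stats = discovery.discover(
        bam, ref_fa,
        min_mapq=cfg.min_mapq, min_support=cfg.min_support, k=cfg.k,
    )
    calls = [
        simulate.CallRecord(
            chrom=p.chrom,
            breakpoint=p.breakpoint,
            parts=(p.left.ins_part_seq, p.right.ins_part_seq),
        )
        for p in pairs
    ]
    from pyfaidx import Fasta

    acceptor_seq = str(
        Fasta(inputs.acceptor_fa, as_raw=True, sequence_always_upper=True)[
            simulate.ACCEPTOR_NAME
        ][:]
    )
    metrics = simulate.evaluate_calls(calls, inputs.truth, acceptor_seq=acceptor_seq)
    log.info(
        "%s condition: sensitivity %.3f, FDR %.3f (%d calls, %d truth) [%s]",
        tag, metrics.sensitivity, metrics.fdr, metrics.n_called, metrics.n_true, stats,
    )
    return metrics
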