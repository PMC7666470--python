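"""VCF output for the traced catalogue and multi-sample genotypes.

Insertions are written sequence-resolved (full ALT allele, not symbolic
<INS>) so the genotyping stage is self-contained. Coordinates follow the
VCF convention: POS is the 1-based base immediately before the insertion,
REF is that base, ALT is REF + inserted sequence.
"""

from __future__ import annotations

import pysam
from pyfaidx import Fasta

from .tracing import TracedInsertion

_INFO_LINES = [
    ('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">'),
    ('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Inserted sequence length">'),
    ('##INFO=<ID=TRACESRC,Number=.,Type=String,Description="Target genomes the insertion was traced to">'),
    ('##INFO=<ID=ANCSTATE,Number=1,Type=String,Description="Ancestral state class">'),
    ('##INFO=<ID=CONCORD,Number=0,Type=Flag,Description="Multi-genome tracings concordant">'),
    ('##INFO=<ID=MECH,Number=1,Type=String,Description="Inferred mutational mechanism">'),
]


def _header(reference_path: str, samples: list[str] | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    ref = Fasta(reference_path, as_raw=True)
    for name in ref.keys():
        header.contigs.add(name, length=len(ref[name]))
    for line in _INFO_LINES:
        header.add_line(line)
    if samples:
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        header.add_line(
            '##FORMAT=<ID=AD,Number=2,Type=Integer,Description="Supporting reads (ref, alt)">'
        )
        for s in samples:
            header.add_sample(s)
    return header


def write_catalogue(
    traced: list[TracedInsertion],
    reference_path: str,
    out_vcf: str,
    mechanisms: dict[str, str] | None = None,
) -> str:
    """Write traced insertions (only those with a resolved sequence) as VCF."""
    header = _header(reference_path)
    ref = Fasta(reference_path, as_raw=True, sequence_always_upper=True)
    with pysam.VariantFile(out_vcf, "w", header=header) as vcf:
        for i, t in enumerate(
            sorted(traced, key=lambda t: (t.chrom, t.left_bp))
        ):
            if not t.full_ins_seq:
                continue
            vid = f"I_{i + 1}"
            anchor = str(ref[t.chrom][t.left_bp - 1 : t.left_bp]) or "N"
            rec = vcf.new_record(
                contig=t.chrom,
                start=t.left_bp - 1,
                alleles=(anchor, anchor + t.full_ins_seq),
                id=vid,
            )
            rec.info["SVTYPE"] = "INS"
            rec.info["SVLEN"] = len(t.full_ins_seq)
            if t.traced_sources:
                rec.info["TRACESRC"] = ",".join(s[0] for s in t.traced_sources)
            rec.info["ANCSTATE"] = t.ancestral_state
            if t.concordant:
                rec.info["CONCORD"] = True
            if mechanisms and vid in mechanisms:
                rec.info["MECH"] = mechanisms[vid]
            vcf.write(rec)
    return out_vcf


def read_catalogue(vcf_path: str) -> list[tuple[str, str, int, str]]:
    """Read a sequence-resolved catalogue: (id, chrom, breakpoint0, ins_seq)."""
    out = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else ""
            if not alt or alt.startswith("<") or len(alt) <= len(rec.ref):
                continue
            ins_seq = alt[len(rec.ref) :]
            out.append((rec.id or f"{rec.contig}:{rec.pos}", rec.contig, rec.pos, ins_seq))
    return out


def write_genotypes(
    catalogue: list[tuple[str, str, int, str]],
    calls_by_sample: dict[str, dict[str, object]],
    reference_path: str,
    out_vcf: str,
) -> str:
    """Write a multi-sample VCF with GT and AD from genotype calls.

    ``calls_by_sample`` maps sample -> {variant_id -> GenotypeCall}.
    """
    samples = sorted(calls_by_sample)
    header = _header(reference_path, samples)
    ref = Fasta(reference_path, as_raw=True, sequence_always_upper=True)
    with pysam.VariantFile(out_vcf, "w", header=header) as vcf:
        for vid, chrom, bp, ins_seq in catalogue:
            anchor = str(ref[chrom][bp - 1 : bp]) or "N"
            rec = vcf.new_record(
                contig=chrom, start=bp - 1, alleles=(anchor, anchor + ins_seq), id=vid
            )
            rec.info["SVTYPE"] = "INS"
            rec.info["SVLEN"] = len(ins_seq)
            for s in samples:
                call = calls_by_sample[s].get(vid)
                if call is None:
                    rec.samples[s]["GT"] = (None, None)
                    continue
                gt = call.gt
                rec.samples[s]["GT"] = {
                    "0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1),
                }.get(gt, (None, None))
                rec.samples[s]["AD"] = (call.n_ref, call.n_alt)
            vcf.write(rec)
    return out_vcf
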