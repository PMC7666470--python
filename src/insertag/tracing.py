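"""Tracing: infer full inserted sequences from target genomes.

For each paired insertion-tag, the reference flanks around the insertion
site are mapped to a target genome to locate the syntenic locus; the target
sequence between the inner flank ends is the candidate full insertion, which
is accepted only when the partial inserted sequences of both tags align to
its corresponding ends. Candidates traced from several genomes are checked
for concordance, and the class of the supporting genomes decides the
ancestral state: presence in a non-human primate genome implies the human
reference carries a deletion of ancestral sequence ("retention of ancestral
sequence"); presence only in other human assemblies or unmapped-contig
databases implies a novel insertion after the human-primate split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pyfaidx import Fasta

from ._seq import global_identity, infix_identity, revcomp
from .discovery import PairedInsertionTag
from .mapping import QueryHit, map_queries

log = logging.getLogger(__name__)

RETENTION = "retention_of_ancestral"
NOVEL = "novel_insertion"
UNTRACED = "untraced"

NONHUMAN_PRIMATE = "nonhuman_primate"
HUMAN_ASSEMBLY = "human_assembly"
UNMAPPED_CONTIG_DB = "unmapped_contig_db"


@dataclass(frozen=True)
class TargetGenome:
    name: str
    fasta: str
    cls: str  # NONHUMAN_PRIMATE | HUMAN_ASSEMBLY | UNMAPPED_CONTIG_DB


@dataclass
class SyntenicLocus:
    target_contig: str
    start: int
    end: int  # half-open interval between the inner flank ends
    strand: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TracedInsertion:
    chrom: str
    left_bp: int
    right_bp: int
    full_ins_seq: str = ""
    traced_sources: list[tuple[str, str, float]] = field(default_factory=list)
    concordant: bool = True
    ancestral_state: str = UNTRACED
    pair: PairedInsertionTag | None = None


def classify_ancestral_state(source_classes: list[str]) -> str:
    """Pure class logic: any primate source wins, then any human source."""
    if NONHUMAN_PRIMATE in source_classes:
        return RETENTION
    if HUMAN_ASSEMBLY in source_classes or UNMAPPED_CONTIG_DB in source_classes:
        return NOVEL
    return UNTRACED


def check_concordance(
    candidates: list[tuple[str, str]], min_identity: float = 0.90
) -> tuple[bool, tuple[str, str]]:
    """All-pairs identity over the shorter length; pick the consensus candidate.

    Concordant iff every pair reaches ``min_identity``. The consensus is the
    candidate with the highest mean pairwise identity; ties break toward the
    longer sequence, then the lexicographically smaller genome name.
    """
    if not candidates:
        raise ValueError("no candidates")
    if len(candidates) == 1:
        return True, candidates[0]
    n = len(candidates)
    ident = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ident[i][j] = ident[j][i] = global_identity(
                candidates[i][1], candidates[j][1]
            )
    concordant = all(ident[i][j] >= min_identity for i in range(n) for j in range(i + 1, n))
    best = max(
        range(n),
        key=lambda i: (
            sum(ident[i][j] for j in range(n) if j != i) / (n - 1),
            len(candidates[i][1]),
            # lexicographically smaller name wins: invert by negative ordinal trick
        ),
    )
    # resolve remaining exact ties by genome name
    best_key = (
        sum(ident[best][j] for j in range(n) if j != best) / (n - 1),
        len(candidates[best][1]),
    )
    tied = [
        i
        for i in range(n)
        if (
            sum(ident[i][j] for j in range(n) if j != i) / (n - 1),
            len(candidates[i][1]),
        )
        == best_key
    ]
    best = min(tied, key=lambda i: candidates[i][0])
    return concordant, candidates[best]


class Tracer:
    """Traces paired insertion-tags against a set of target genomes."""

    def __init__(
        self,
        reference_fasta: str,
        genomes: list[TargetGenome],
        flank_len: int = 500,
        unique_mapq: int = 20,
        min_identity: float = 0.90,
        max_insertion: int = 100_000,
    ) -> None:
        self.ref = Fasta(reference_fasta, as_raw=True, sequence_always_upper=True)
        self.genomes = list(genomes)
        self.flank_len = flank_len
        self.unique_mapq = unique_mapq
        self.min_identity = min_identity
        self.max_insertion = max_insertion
        self._targets: dict[str, Fasta] = {}

    def _target_fasta(self, genome: TargetGenome) -> Fasta:
        if genome.name not in self._targets:
            self._targets[genome.name] = Fasta(
                genome.fasta, as_raw=True, sequence_always_upper=True
            )
        return self._targets[genome.name]

    def _flanks(self, pair: PairedInsertionTag) -> tuple[str, str] | None:
        # both flanks are taken in the left-anchored frame: when the two tag
        # breakpoints disagree (microhomology), the traced sequence is then
        # the left-anchored representation of the insertion
        chrom = pair.chrom
        left_bp = pair.site[0]
        clen = len(self.ref[chrom])
        if left_bp - self.flank_len < 0 or left_bp + self.flank_len > clen:
            log.info("flank extraction beyond contig end at %s:%d", chrom, left_bp)
            return None
        left = str(self.ref[chrom][left_bp - self.flank_len : left_bp])
        right = str(self.ref[chrom][left_bp : left_bp + self.flank_len])
        return left, right

    def locate_syntenic_region(
        self, pair: PairedInsertionTag, genome: TargetGenome
    ) -> SyntenicLocus | None:
        flanks = self._flanks(pair)
        if flanks is None:
            return None
        hits = map_queries(genome.fasta, {"L": flanks[0], "R": flanks[1]})
        return self._locus_from_hits(hits.get("L", []), hits.get("R", []))

    def _unique_hit(self, hits: list[QueryHit]) -> QueryHit | None:
        strong = [h for h in hits if h.mapq >= self.unique_mapq]
        if len(strong) != 1:
            return None
        return strong[0]

    def _locus_from_hits(
        self, lhits: list[QueryHit], rhits: list[QueryHit]
    ) -> SyntenicLocus | None:
        lh, rh = self._unique_hit(lhits), self._unique_hit(rhits)
        if lh is None or rh is None:
            return None
        if lh.target != rh.target or lh.strand != rh.strand:
            return None
        if lh.strand == "+":
            # account for query bases soft-clipped at the junction-facing end
            start = lh.end + (lh.query_len - lh.query_end)
            end = rh.start - rh.query_start
        else:
            start = rh.end + rh.query_start
            end = lh.start - (lh.query_len - lh.query_end)
        if end < start or end - start > self.max_insertion:
            return None
        return SyntenicLocus(lh.target, start, end, lh.strand)

    def _candidate_seq(self, genome: TargetGenome, locus: SyntenicLocus) -> str:
        fa = self._target_fasta(genome)
        seq = str(fa[locus.target_contig][locus.start : locus.end])
        return revcomp(seq) if locus.strand == "-" else seq

    def _parts_match(self, pair: PairedInsertionTag, cand: str) -> float | None:
        """Identity of the tag ins_parts against the candidate's two ends."""
        lp = pair.left.ins_part_seq
        rp = pair.right.ins_part_seq
        if not lp and not rp:
            return None
        if not cand:
            return None
        idents = []
        if lp:
            window = cand[: min(len(cand), len(lp) + 50)]
            ident = infix_identity(lp[: len(cand)], window) if len(lp) > len(cand) \
                else infix_identity(lp, window)
            idents.append(ident)
        if rp:
            window = cand[-min(len(cand), len(rp) + 50):]
            ident = infix_identity(rp[-len(cand):], window) if len(rp) > len(cand) \
                else infix_identity(rp, window)
            idents.append(ident)
        if any(i < self.min_identity for i in idents):
            return None
        return sum(idents) / len(idents)

    def trace_insertion(self, pair: PairedInsertionTag) -> TracedInsertion:
        return self.trace_catalogue([pair])[0]

    def trace_catalogue(self, pairs: list[PairedInsertionTag]) -> list[TracedInsertion]:
        """Trace many pairs, batching one aligner run per target genome."""
        traced = [
            TracedInsertion(chrom=p.chrom, left_bp=p.site[0], right_bp=p.site[1], pair=p)
            for p in pairs
        ]
        flank_queries: dict[str, str] = {}
        usable: list[int] = []
        for i, p in enumerate(pairs):
            fl = self._flanks(p)
            if fl is None:
                continue
            flank_queries[f"{i}:L"] = fl[0]
            flank_queries[f"{i}:R"] = fl[1]
            usable.append(i)
        candidates: dict[int, list[tuple[str, str, float]]] = {i: [] for i in usable}
        for genome in self.genomes:
            hits = map_queries(genome.fasta, flank_queries)
            for i in usable:
                locus = self._locus_from_hits(
                    hits.get(f"{i}:L", []), hits.get(f"{i}:R", [])
                )
                if locus is None:
                    continue
                cand = self._candidate_seq(genome, locus)
                ident = self._parts_match(pairs[i], cand)
                if ident is None:
                    continue
                locus_str = f"{locus.target_contig}:{locus.start}-{locus.end}({locus.strand})"
                candidates[i].append((genome.name, cand, ident))
                traced[i].traced_sources.append((genome.name, locus_str, ident))
        cls_by_name = {g.name: g.cls for g in self.genomes}
        for i in usable:
            cands = candidates[i]
            if not cands:
                continue
            concordant, (_, consensus) = check_concordance(
                [(name, seq) for name, seq, _ in cands], self.min_identity
            )
            traced[i].full_ins_seq = consensus
            traced[i].concordant = concordant
            traced[i].ancestral_state = classify_ancestral_state(
                [cls_by_name[name] for name, _, _ in cands]
            )
        return traced
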