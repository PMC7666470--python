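"""Strand-specific local De Bruijn assembly for discordant-PER clusters.

Reads are assumed pre-oriented into a single genome-forward frame, so the
graph is built on one strand only (no canonical k-mers). Contigs are maximal
unbranched paths after two cleaning steps:

* relative branch pruning -- at a fork, an edge whose coverage is below
  ``prune_ratio`` times its strongest sibling is cut (removes sequencing-error
  bubbles and tips without an absolute coverage floor, which matters because
  breakpoint-spanning k-mers in a discordant-only cluster may be covered by a
  single read);
* tip clipping -- a dead-end unitig shorter than ``2k`` hanging off a branch
  is removed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib

from ._seq import revcomp

_BASES = "ACGT"


@dataclass
class Contig:
    seq: str
    k: int
    read_placements: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


def kmer_counts(reads: list[tuple[str, str]], k: int) -> Counter:
    """Count k-mers over all read sequences; k-mers containing N are skipped."""
    counts: Counter[str] = Counter()
    for _, seq in reads:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" not in km:
                counts[km] += 1
    return counts


def _build_edges(counts: Counter, min_count: int, prune_ratio: float):
    out_e: dict[str, dict[str, int]] = defaultdict(dict)
    in_e: dict[str, dict[str, int]] = defaultdict(dict)
    for km, c in counts.items():
        if c < min_count:
            continue
        out_e[km[:-1]][km[-1]] = c
        in_e[km[1:]][km[0]] = c
    # Relative pruning at forks, in both directions.
    doomed: set[str] = set()
    for node, edges in out_e.items():
        if len(edges) > 1:
            top = max(edges.values())
            for b, c in edges.items():
                if c < prune_ratio * top:
                    doomed.add(node + b)
    for node, edges in in_e.items():
        if len(edges) > 1:
            top = max(edges.values())
            for b, c in edges.items():
                if c < prune_ratio * top:
                    doomed.add(b + node)
    if doomed:
        for km in doomed:
            out_e[km[:-1]].pop(km[-1], None)
            in_e[km[1:]].pop(km[0], None)
    return out_e, in_e


def _unitigs(out_e, in_e) -> list[str]:
    """Enumerate maximal unbranched paths of the graph, deterministically."""

    def outdeg(n):
        return len(out_e.get(n, ()))

    def indeg(n):
        return len(in_e.get(n, ()))

    nodes = set(out_e) | set(in_e)
    paths: list[str] = []
    visited_edges: set[tuple[str, str]] = set()

    def walk(start: str) -> None:
        for b in sorted(out_e.get(start, ())):
            if (start, b) in visited_edges:
                continue
            seq = [start, b]
            visited_edges.add((start, b))
            node = start[1:] + b
            while indeg(node) == 1 and outdeg(node) == 1:
                (nb,) = out_e[node].keys()
                if (node, nb) in visited_edges:
                    break
                visited_edges.add((node, nb))
                seq.append(nb)
                node = node[1:] + nb
            paths.append("".join(seq))

    starts = sorted(n for n in nodes if not (indeg(n) == 1 and outdeg(n) == 1))
    for n in starts:
        walk(n)
    # Isolated simple cycles: open them at the lexicographically smallest node.
    for n in sorted(nodes):
        if any((n, b) not in visited_edges for b in out_e.get(n, ())):
            walk(n)
    return paths


def _clip_tips(
    paths: list[str], out_e, in_e, k: int, counts: Counter, tip_ratio: float = 0.25
) -> list[str]:
    """Drop short dead-end paths much weaker than their sibling branch.

    A genuine terminal segment (e.g. a contig end) is also a dead end, so a
    tip is only clipped when its own k-mer coverage is below ``tip_ratio``
    times the strongest competing edge at the node it hangs off.
    """

    def outdeg(n):
        return len(out_e.get(n, ()))

    def indeg(n):
        return len(in_e.get(n, ()))

    def mean_cov(p):
        kms = [p[i : i + k] for i in range(len(p) - k + 1)]
        return sum(counts[km] for km in kms) / max(1, len(kms))

    kept = []
    for p in paths:
        if len(p) >= 2 * k:
            kept.append(p)
            continue
        first, last = p[: k - 1], p[-(k - 1) :]
        sibling = 0
        if indeg(first) == 0 and outdeg(last) >= 1 and indeg(last) > 1:
            # dead start, attached at the end: competing in-edges of `last`
            sibling = max(
                counts.get(b + last, 0)
                for b in in_e.get(last, {})
                if b + last != p[-k:]
            ) if len(in_e.get(last, {})) > 1 else 0
        elif outdeg(last) == 0 and indeg(first) >= 1 and outdeg(first) > 1:
            sibling = max(
                counts.get(first + b, 0)
                for b in out_e.get(first, {})
                if first + b != p[: k]
            ) if len(out_e.get(first, {})) > 1 else 0
        if sibling and mean_cov(p) < tip_ratio * sibling:
            continue
        kept.append(p)
    return kept


def place_reads(
    contig_seq: str,
    reads: list[tuple[str, str]],
    max_mismatch_frac: float = 0.10,
) -> list[tuple[str, int, str]]:
    """Best placement of each read on a contig, trying both orientations."""
    placements = []
    for rid, seq in reads:
        best = None
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            budget = int(max_mismatch_frac * min(len(s), len(contig_seq)))
            if len(s) <= len(contig_seq):
                res = edlib.align(s, contig_seq, mode="HW", task="locations", k=budget)
                if res["editDistance"] >= 0:
                    start = res["locations"][0][0]
                else:
                    continue
            else:
                # contig shorter than the read: place by containment
                res = edlib.align(contig_seq, s, mode="HW", task="locations", k=budget)
                if res["editDistance"] >= 0:
                    start = -res["locations"][0][0]
                else:
                    continue
            d = res["editDistance"]
            if best is None or d < best[0]:
                best = (d, rid, start, strand)
        if best is not None:
            placements.append((best[1], best[2], best[3]))
    return placements


def assemble(
    reads: list[tuple[str, str]],
    k: int = 31,
    min_kmer_count: int = 1,
    prune_ratio: float = 0.2,
    min_contig_len: int | None = None,
    with_placements: bool = True,
) -> list[Contig]:
    """Assemble oriented reads into contigs.

    Returns contigs sorted by descending number of placed reads, then length.
    """
    if k % 2 == 0 or k < 5:
        raise ValueError(f"k must be odd and >= 5, got {k}")
    counts = kmer_counts(reads, k)
    if not counts:
        return []
    out_e, in_e = _build_edges(counts, min_kmer_count, prune_ratio)
    paths = _unitigs(out_e, in_e)
    paths = _clip_tips(paths, out_e, in_e, k, counts)
    min_len = min_contig_len if min_contig_len is not None else k + 10
    contigs = [Contig(seq=p, k=k) for p in paths if len(p) >= min_len]
    if with_placements:
        for c in contigs:
            c.read_placements = place_reads(c.seq, reads)
        contigs = [c for c in contigs if c.read_placements]
        contigs.sort(key=lambda c: (-len(c.read_placements), -len(c.seq), c.seq))
    else:
        contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    return contigs
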