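"""Mutational-mechanism inference from breakpoint sequence features.

Each insertion variant is assigned exactly one mechanism by a fixed priority
cascade: VNTR (tandem expansion sharing its motif with the insertion site),
then NAHR (homologous breakpoint flanks), then TE (insertion more than 80%
covered by annotated retroelements such as Alu/L1/SVA), and finally NH
(non-homologous, no recognizable feature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyfaidx import Fasta

import edlib

VNTR, NAHR, TE, NH = "VNTR", "NAHR", "TE", "NH"


@dataclass(frozen=True)
class MechanismCall:
    variant_id: str
    mech: str
    evidence: dict


def extract_breakpoint_context(
    chrom: str, pos: int, reference: Fasta, w: int = 100
) -> tuple[str, str, bool]:
    """Return w bp of reference on each side of the insertion site.

    Flanks are truncated (and flagged) near contig edges.
    """
    clen = len(reference[chrom])
    left = str(reference[chrom][max(0, pos - w) : pos])
    right = str(reference[chrom][pos : min(clen, pos + w)])
    truncated = len(left) < w or len(right) < w
    return left, right, truncated


def tandem_coverage(seq: str, period: int) -> float:
    """Fraction of the sequence covered by tandem copies at a given period.

    Measured as the self-match rate at lag ``period``: positions agreeing
    with the base one period earlier, plus the seed copy itself.
    """
    n = len(seq)
    if period >= n:
        return 0.0
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    matches = int(np.count_nonzero(a[period:] == a[:-period]))
    return (matches + period) / n


def detect_vntr(
    ins_seq: str,
    flanks: tuple[str, str],
    min_coverage: float = 0.85,
    max_period: int = 2000,
) -> tuple[int, int] | None:
    """Detect a tandem-repeat insertion whose motif recurs at the site flank.

    Scans all periods p in [2, len/2]; the smallest period whose tandem
    coverage reaches ``min_coverage`` and whose consensus motif occurs in the
    breakpoint-adjacent flank wins. Returns (period, copy_number) or None.
    """
    n = len(ins_seq)
    left, right = flanks
    for p in range(2, min(n // 2, max_period) + 1):
        if tandem_coverage(ins_seq, p) < min_coverage:
            continue
        motif = _consensus_motif(ins_seq, p)
        near = left[-4 * p :] + "|" + right[: 4 * p]
        if motif in near:
            return p, round(n / p)
    return None


def _consensus_motif(seq: str, period: int) -> str:
    """Most frequent phase-aligned p-mer of the sequence."""
    from collections import Counter

    counts = Counter(
        seq[i : i + period]
        for i in range(0, len(seq) - period + 1, period)
    )
    return counts.most_common(1)[0][0]


def detect_nahr(
    left_flank: str,
    right_flank: str,
    min_homology: int = 50,
    min_identity: float = 0.90,
) -> int | None:
    """Longest high-identity ungapped alignment between the two flanks.

    Returns the homology length when it reaches ``min_homology``, else None.
    """
    best = _longest_homology(left_flank, right_flank, min_identity)
    return best if best >= min_homology else None


def _longest_homology(a: str, b: str, min_identity: float) -> int:
    if not a or not b:
        return 0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    n, m = len(x), len(y)
    best = 0
    for shift in range(-(n - 1), m):
        lo = max(0, -shift)
        hi = min(n, m - shift)
        if hi - lo <= best:
            continue
        match = (x[lo:hi] == y[lo + shift : hi + shift]).astype(np.int32)
        cum = np.concatenate([[0], np.cumsum(match)])
        ln = len(match)
        # longest window with identity >= min_identity
        for i in range(ln):
            width = ln - i
            if width <= best:
                break
            js = np.arange(i + best + 1, ln + 1)
            if js.size == 0:
                continue
            ident = (cum[js] - cum[i]) / (js - i)
            ok = np.nonzero(ident >= min_identity)[0]
            if ok.size:
                best = int(js[ok[-1]] - i)
    return best


def classify_te(
    svlen: int,
    repeat_annotation: list[tuple[int, int, str]],
    min_fraction: float = 0.80,
) -> tuple[float, str] | None:
    """TE call from a repeat annotation on the insertion sequence.

    ``repeat_annotation`` holds half-open intervals (start, end, family) on
    the insertion; the covered fraction is computed on the interval union and
    must strictly exceed ``min_fraction``. The family is the majority element
    class by covered bp. Missing/empty annotation -> None.
    """
    if not repeat_annotation or svlen <= 0:
        return None
    events: list[tuple[int, int, str]] = [
        (max(0, s), min(svlen, e), fam) for s, e, fam in repeat_annotation if e > s
    ]
    if not events:
        return None
    points = sorted({p for s, e, _ in events for p in (s, e)})
    covered = 0
    fam_bp: dict[str, int] = {}
    for s, e in zip(points, points[1:]):
        active = [fam for fs, fe, fam in events if fs <= s and fe >= e]
        if active:
            covered += e - s
            for fam in set(active):
                fam_bp[fam] = fam_bp.get(fam, 0) + e - s
    fraction = covered / svlen
    if fraction <= min_fraction:
        return None
    family = max(fam_bp.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return fraction, family


def classify_mechanism(
    variant_id: str,
    ins_seq: str,
    flanks: tuple[str, str],
    repeat_annotation: list[tuple[int, int, str]] | None = None,
    vntr_min_coverage: float = 0.85,
    nahr_min_homology: int = 50,
    te_min_fraction: float = 0.80,
) -> MechanismCall:
    """Priority cascade VNTR -> NAHR -> TE -> NH; first positive wins."""
    vntr = detect_vntr(ins_seq, flanks, min_coverage=vntr_min_coverage)
    if vntr is not None:
        period, copies = vntr
        return MechanismCall(variant_id, VNTR, {"period": period, "copies": copies})
    nahr = detect_nahr(flanks[0], flanks[1], min_homology=nahr_min_homology)
    if nahr is not None:
        return MechanismCall(variant_id, NAHR, {"homology_len": nahr})
    te = classify_te(len(ins_seq), repeat_annotation or [], min_fraction=te_min_fraction)
    if te is not None:
        fraction, family = te
        return MechanismCall(variant_id, TE, {"fraction": round(fraction, 4), "family": family})
    return MechanismCall(variant_id, NH, {})


def motif_annotator(
    ins_seq: str,
    library: dict[str, str],
    min_identity: float = 0.80,
    max_hits: int = 50,
) -> list[tuple[int, int, str]]:
    """Toy repeat annotator: greedy masking search of library elements.

    A pluggable stand-in for an external repeat annotation (the real
    interface is a BED of intervals on the insertion sequence): each library
    element is aligned repeatedly into the unmasked insertion and hits at
    >= ``min_identity`` are emitted as intervals.
    """
    intervals: list[tuple[int, int, str]] = []
    masked = ins_seq
    for name, elem in sorted(library.items(), key=lambda kv: -len(kv[1])):
        max_dist = int((1 - min_identity) * len(elem))
        for _ in range(max_hits):
            res = edlib.align(elem, masked, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] < 0:
                break
            s, e = res["locations"][0]
            e += 1
            if e - s < min_identity * len(elem):
                break
            intervals.append((s, e, name))
            masked = masked[:s] + "#" * (e - s) + masked[e:]
    return sorted(intervals)
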