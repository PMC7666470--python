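"""Simulation of genomes, insertions, and paired-end reads, plus scoring.

The generator emulates the benchmark conditions the discovery stage is
validated under: a synthetic acceptor chromosome receives implanted segments
drawn from a synthetic donor chromosome (log-uniform sizes), paired-end
reads are sampled from the mutated acceptor, and calls are scored against
the implant truth set with the matching rules: a call is true when its
breakpoint lies within 100 bp of an implant and at least half of its
predicted insertion sequence aligns to the implanted segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

ACCEPTOR_NAME = "acceptor"
DONOR_NAME = "donor"

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b


def default_repeat_library(
    seed: int = 777,
    n_families: int = 1200,
    size_range: tuple[int, int] = (300, 3000),
) -> dict[str, str]:
    """Synthetic interspersed-repeat library (stand-in for Alu/L1/SVA-like
    element families; all sequences are randomly generated).

    Deterministic regardless of the simulation seed so that genomes built in
    separate calls share the same families: when an acceptor and a donor each
    carry a near-identical copy of a family, adding the donor to the mapping
    reference creates genuine multi-mapping, which is what makes the
    non-unique benchmark condition harder than the unique one.
    """
    rng = np.random.default_rng(seed)
    sizes = np.exp(
        rng.uniform(np.log(size_range[0]), np.log(size_range[1]), n_families)
    ).astype(int)
    lib = {}
    for i, size in enumerate(sizes):
        seq = _BASE_ARR[rng.integers(0, 4, size)].tobytes().decode()
        lib[f"synREP{i}"] = seq
    return lib


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    a = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(a)) < rate
    idx = np.nonzero(mask)[0]
    if idx.size:
        # substitute with a strictly different base
        cur = np.searchsorted(_BASE_ARR, a[idx])
        cur[cur > 3] = 0
        new = (cur + rng.integers(1, 4, idx.size)) % 4
        a[idx] = _BASE_ARR[new]
    return a.tobytes().decode()


def generate_synthetic_genome(
    length: int,
    gc: float = 0.41,
    repeat_density: float = 0.2,
    seed: int = 0,
    repeat_library: dict[str, str] | None = None,
    copy_divergence: float = 0.002,
) -> str:
    """I.i.d. background at the given GC with interspersed repeat copies.

    Families are drawn from the library in a shuffled order without
    replacement (cycling only when the library is exhausted), so two genomes
    built from the same library mostly carry one near-identical copy of each
    family each. Copies diverge from the consensus by ``copy_divergence``
    substitutions and are placed without overlap until approximately
    ``repeat_density`` of the sequence is repeat-derived. Deterministic for a
    fixed seed.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kbp")
    if not 0 <= repeat_density < 1:
        raise ValueError(f"repeat_density must be in [0, 1), got {repeat_density}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = _BASE_ARR[rng.choice(4, size=length, p=p)].copy()
    if repeat_density > 0:
        lib = repeat_library if repeat_library is not None else default_repeat_library()
        names = sorted(lib)
        order = list(rng.permutation(len(names)))
        occupied = np.zeros(length, dtype=bool)
        covered = 0
        target = int(repeat_density * length)
        tries = 0
        cursor = 0
        while covered < target and tries < 100_000:
            tries += 1
            if cursor >= len(order):
                cursor = 0
                order = list(rng.permutation(len(names)))
            name = names[order[cursor]]
            copy = _mutate(lib[name], copy_divergence, rng)
            ln = len(copy)
            if ln >= length:
                cursor += 1
                continue
            pos = int(rng.integers(0, length - ln))
            if occupied[pos : pos + ln].any():
                continue
            genome[pos : pos + ln] = np.frombuffer(copy.encode(), dtype=np.uint8)
            occupied[pos : pos + ln] = True
            covered += ln
            cursor += 1
    return genome.tobytes().decode()


@dataclass(frozen=True)
class TruthRecord:
    position: int  # acceptor coordinate (original frame) of the insertion point
    donor_start: int
    donor_end: int
    seq: str


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("position\tdonor_start\tdonor_end\tlength\tseq\n")
            for r in self.records:
                fh.write(
                    f"{r.position}\t{r.donor_start}\t{r.donor_end}\t{len(r.seq)}\t{r.seq}\n"
                )

    @classmethod
    def from_tsv(cls, path: str) -> "TruthSet":
        recs = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                pos, ds, de, _, seq = line.rstrip("\n").split("\t")
                recs.append(TruthRecord(int(pos), int(ds), int(de), seq))
        return cls(recs)


def implant_insertions(
    acceptor: str,
    donor: str,
    n: int,
    size_min: int = 100,
    size_max: int = 20_000,
    seed: int = 0,
    min_gap: int = 2_000,
    edge_margin: int = 10_000,
) -> tuple[str, TruthSet]:
    """Implant n donor segments into the acceptor at non-overlapping sites.

    Sizes are log-uniform in [size_min, size_max]; insertion points are
    uniform with a minimum pairwise separation (so neighboring events do not
    share discordant-read windows) and truth coordinates are recorded on the
    original acceptor frame. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sizes = np.exp(
        rng.uniform(np.log(size_min), np.log(size_max), size=n)
    ).astype(int)
    sizes = np.clip(sizes, size_min, size_max)
    positions: list[int] = []
    for _ in range(200_000):
        if len(positions) == n:
            break
        cand = int(rng.integers(edge_margin, len(acceptor) - edge_margin))
        if all(abs(cand - p) >= min_gap for p in positions):
            positions.append(cand)
    if len(positions) < n:
        raise RuntimeError(
            f"could not place {n} non-overlapping insertions in a "
            f"{len(acceptor)} bp acceptor"
        )
    positions.sort()
    records: list[TruthRecord] = []
    for pos, size in zip(positions, sizes):
        ds = int(rng.integers(0, len(donor) - size))
        records.append(TruthRecord(pos, ds, ds + int(size), donor[ds : ds + int(size)]))
    pieces: list[str] = []
    prev = 0
    for r in records:
        pieces.append(acceptor[prev : r.position])
        pieces.append(r.seq)
        prev = r.position
    pieces.append(acceptor[prev:])
    return "".join(pieces), TruthSet(records)


def simulate_pers(
    genome: str,
    out_fastq1: str,
    out_fastq2: str,
    coverage: float = 30.0,
    read_len: int = 100,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    err: float = 0.002,
    seed: int = 0,
    name_prefix: str = "sim",
) -> int:
    """Simulate FR paired-end reads to a target coverage; returns pair count.

    Fragment starts are uniform (a Poisson process over the genome), insert
    sizes normal, substitution errors i.i.d. per base. Deterministic per seed.
    """
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed twice the read length")
    rng = np.random.default_rng(seed)
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    glen = len(g)
    n = int(round(coverage * glen / (2 * read_len)))
    inserts = np.clip(
        rng.normal(insert_mean, insert_sd, n).astype(int), read_len, glen - 1
    )
    starts = (rng.random(n) * (glen - inserts)).astype(int)
    offs = np.arange(read_len)
    r1 = g[starts[:, None] + offs]
    r2 = g[(starts + inserts - read_len)[:, None] + offs]
    r2 = _COMP_TABLE[r2[:, ::-1]]
    for arr in (r1, r2):
        if err > 0:
            mask = rng.random(arr.shape) < err
            ii = np.nonzero(mask)
            if ii[0].size:
                cur = np.searchsorted(_BASE_ARR, arr[ii])
                cur[cur > 3] = 0
                arr[ii] = _BASE_ARR[(cur + rng.integers(1, 4, ii[0].size)) % 4]
    qual = "I" * read_len
    for path, arr in ((out_fastq1, r1), (out_fastq2, r2)):
        rows = arr.view(f"S{read_len}").ravel()
        with open(path, "w") as fh:
            chunk: list[str] = []
            for i, row in enumerate(rows):
                chunk.append(f"@{name_prefix}_{i}\n{row.decode()}\n+\n{qual}\n")
                if len(chunk) >= 20_000:
                    fh.write("".join(chunk))
                    chunk = []
            fh.write("".join(chunk))
    return n


@dataclass
class EvalMetrics:
    sensitivity: float
    fdr: float
    breakpoint_gaps: list[int]
    n_true: int
    n_called: int
    n_matched: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass(frozen=True)
class CallRecord:
    chrom: str
    breakpoint: int
    parts: tuple[str, ...]  # predicted (possibly partial) insertion sequences


_local_aligner = None


def _get_local_aligner():
    global _local_aligner
    if _local_aligner is None:
        from Bio import Align

        _local_aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-2,
            open_gap_score=-2, extend_gap_score=-1,
        )
    return _local_aligner


def _aligned_fraction(parts: tuple[str, ...], truth_seq: str) -> float:
    """Fraction of the predicted insertion bases locally aligned to the truth.

    Each predicted part is aligned (Smith-Waterman) against the truth
    segment; matched bases over total predicted length. Long truth segments
    are probed at both ends, where partial tag sequences must originate.
    """
    total = sum(len(p) for p in parts)
    if total == 0 or not truth_seq:
        return 0.0
    if len(truth_seq) > 4500:
        windows = [truth_seq[:2200], truth_seq[-2200:]]
    else:
        windows = [truth_seq]
    aligner = _get_local_aligner()
    aligned = 0.0
    for p in parts:
        if not p:
            continue
        best = 0
        for w in windows:
            alns = aligner.align(p, w)
            if len(alns) == 0:
                continue
            best = max(best, alns[0].counts().identities)
        aligned += min(best, len(p))
    return aligned / total


def _equivalence_interval(acceptor: str | None, rec: TruthRecord) -> tuple[int, int]:
    """Breakpoint positions equivalent to an implant under microhomology.

    Inserting S at p yields the same mutated sequence as inserting a rotation
    of S at p+h when S's prefix matches the acceptor after p (and mirrored on
    the left), so any breakpoint inside the interval is exact.
    """
    p = rec.position
    if acceptor is None or not rec.seq:
        return p, p
    s = rec.seq
    hi = p
    while hi - p < len(s) and hi < len(acceptor) and s[(hi - p) % len(s)] == acceptor[hi]:
        hi += 1
    lo = p
    while p - lo < len(s) and lo > 0 and s[-((p - lo) % len(s)) - 1] == acceptor[lo - 1]:
        lo -= 1
    return lo, hi


def evaluate_calls(
    calls: list[CallRecord],
    truth: TruthSet,
    acceptor_chrom: str = ACCEPTOR_NAME,
    max_gap: int = 100,
    min_aligned: float = 0.5,
    acceptor_seq: str | None = None,
) -> EvalMetrics:
    """Score calls against the implant truth set.

    A call is eligible for a truth record when its breakpoint gap is strictly
    below ``max_gap`` and at least ``min_aligned`` of its predicted insertion
    sequence aligns to the implanted segment; matching is one-to-one, greedy
    by smallest gap. Sensitivity = matched/n_true, FDR = unmatched/n_called.
    When ``acceptor_seq`` is given, gaps are measured against each implant's
    microhomology equivalence interval (a breakpoint anywhere inside it
    denotes the identical variant and counts as gap 0).
    """
    intervals = [_equivalence_interval(acceptor_seq, rec) for rec in truth.records]
    eligible: list[tuple[int, int, int]] = []
    for ci, call in enumerate(calls):
        if call.chrom != acceptor_chrom:
            continue
        for ti, rec in enumerate(truth.records):
            lo, hi = intervals[ti]
            gap = max(lo - call.breakpoint, call.breakpoint - hi, 0)
            if gap >= max_gap:
                continue
            if _aligned_fraction(call.parts, rec.seq) < min_aligned:
                continue
            eligible.append((gap, ci, ti))
    eligible.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    gaps: list[int] = []
    for gap, ci, ti in eligible:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        gaps.append(gap)
    n_matched = len(gaps)
    n_true = len(truth)
    n_called = len(calls)
    return EvalMetrics(
        sensitivity=n_matched / n_true if n_true else 0.0,
        fdr=(n_called - n_matched) / n_called if n_called else 0.0,
        breakpoint_gaps=gaps,
        n_true=n_true,
        n_called=n_called,
        n_matched=n_matched,
    )


def write_fasta(path: str, records: dict[str, str], width: int = 80) -> str:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path
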