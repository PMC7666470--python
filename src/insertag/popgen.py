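"""Population summaries of genotyped insertion variants.

Works on a biallelic dosage matrix (variants x samples, dosages 0/1/2 with
missing entries), a sample-to-population map, and per-variant insertion
lengths. Provides allele frequencies (overall or per population), the
per-individual non-reference sequence load, and Nei's pairwise F_ST between
one population and the rest: F_ST = (H_T - H_S)/H_T where H_S is the mean
within-group expected heterozygosity and H_T the expected heterozygosity at
the mean of the two group frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    dosages: np.ndarray  # (n_variants, n_samples) int, MISSING for no-call
    variant_ids: list[str]
    sample_ids: list[str]
    lengths: np.ndarray  # per-variant insertion length (bp)
    populations: dict[str, str] = field(default_factory=dict)  # sample -> pop

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=int)
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.populations:
            unlabeled = [s for s in self.sample_ids if s not in self.populations]
            if unlabeled:
                raise ValueError(f"samples without population label: {unlabeled}")

    def sample_mask(self, pops: list[str]) -> np.ndarray:
        return np.array([self.populations[s] in pops for s in self.sample_ids])


def _freq(dos: np.ndarray) -> np.ndarray:
    """Alt allele frequency per variant; NaN when all calls are missing."""
    obs = dos != MISSING
    n_alleles = 2 * obs.sum(axis=1)
    alt = np.where(obs, dos, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def allele_frequencies(gm: GenotypeMatrix, by_group: bool = False) -> pd.DataFrame:
    """Per-variant alt allele frequency, overall or per population."""
    if not by_group:
        return pd.DataFrame({"AF": _freq(gm.dosages)}, index=gm.variant_ids)
    pops = sorted(set(gm.populations[s] for s in gm.sample_ids))
    cols = {}
    for pop in pops:
        cols[pop] = _freq(gm.dosages[:, gm.sample_mask([pop])])
    return pd.DataFrame(cols, index=gm.variant_ids)


def per_individual_load(gm: GenotypeMatrix, dosage_weighted: bool = False) -> pd.DataFrame:
    """Non-reference sequence per sample: bp carried and variant count.

    Presence-based by default (a variant counts its full length once when the
    dosage is >= 1); ``dosage_weighted`` counts length x dosage instead.
    """
    dos = gm.dosages
    present = (dos >= 1).astype(int)
    weights = dos.clip(min=0) if dosage_weighted else present
    bp = (weights * gm.lengths[:, None]).sum(axis=0)
    counts = present.sum(axis=0)
    return pd.DataFrame(
        {"n_variants": counts, "load_bp": bp}, index=gm.sample_ids
    )


def nei_fst(p1: float | np.ndarray, p2: float | np.ndarray) -> float | np.ndarray:
    """Nei F_ST for two allele frequencies: (H_T - H_S)/H_T, 0 if monomorphic."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, 0.0)
    return float(fst) if fst.ndim == 0 else fst


def pairwise_fst(
    gm: GenotypeMatrix, group: str, rest: list[str] | None = None,
    min_samples: int = 2,
) -> pd.Series:
    """Per-variant Nei F_ST between one population group and all others."""
    all_pops = set(gm.populations[s] for s in gm.sample_ids)
    if group not in all_pops:
        raise ValueError(f"population {group!r} not present in sample labels")
    rest_pops = rest if rest is not None else sorted(all_pops - {group})
    missing = [p for p in rest_pops if p not in all_pops]
    if missing:
        raise ValueError(f"population(s) {missing} not present in sample labels")
    d1 = gm.dosages[:, gm.sample_mask([group])]
    d2 = gm.dosages[:, gm.sample_mask(rest_pops)]
    p1, p2 = _freq(d1), _freq(d2)
    enough = ((d1 != MISSING).sum(axis=1) >= min_samples) & (
        (d2 != MISSING).sum(axis=1) >= min_samples
    )
    fst = nei_fst(p1, p2)
    fst = np.where(enough, fst, np.nan)
    return pd.Series(fst, index=gm.variant_ids, name=f"FST_{group}_vs_rest")


def top_fst_report(fst_table: pd.DataFrame, k: int = 10) -> dict[str, pd.Series]:
    """Top-k variants by descending F_ST per group column; ties by variant id."""
    out = {}
    for col in fst_table.columns:
        s = fst_table[col].dropna()
        ranked = s.to_frame("fst").reset_index(names="variant")
        ranked = ranked.sort_values(["fst", "variant"], ascending=[False, True])
        top = ranked.head(k).set_index("variant")["fst"]
        out[col] = top
    return out


def load_population_map(tsv_path: str) -> dict[str, str]:
    """Two-column TSV (sample, population), no header required."""
    pops: dict[str, str] = {}
    with open(tsv_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and parts[0].lower() != "sample":
                pops[parts[0]] = parts[1]
    return pops
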