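"""ORF-level RNA-Seq / Ribo-Seq correlation structure.

Input is a per-ORF abundance table (orf_id, rna, ribo; normalized
nonnegative reads).  Correlations are computed on log10 values with pairwise
exclusion of zero/missing entries; a +1 pseudocount mode is available behind
a flag instead of exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats_core import pearson

__all__ = [
    "read_abundance",
    "pair_correlation",
    "occupancy_comparison",
    "kozak_vs_footprint",
    "OccupancyResult",
    "FootprintCorrelation",
]


def read_abundance(path) -> pd.DataFrame:
    """Load a TSV with columns orf_id, rna, ribo; orf_id becomes the index."""
    df = pd.read_csv(path, sep="\t")
    if not {"orf_id", "rna", "ribo"} <= set(df.columns):
        raise ValueError("abundance table needs columns orf_id, rna, ribo")
    if df["orf_id"].duplicated().any():
        raise ValueError("duplicate orf_id in abundance table")
    if (df[["rna", "ribo"]] < 0).any().any():
        raise ValueError("negative abundance values")
    return df.set_index("orf_id")


def _paired_values(table: pd.DataFrame, pairs, assay: str, pseudocount: float):
    a, b = [], []
    for id1, id2 in pairs:
        if id1 not in table.index or id2 not in table.index:
            continue
        v1 = float(table.at[id1, assay]) + pseudocount
        v2 = float(table.at[id2, assay]) + pseudocount
        if v1 > 0 and v2 > 0 and np.isfinite(v1) and np.isfinite(v2):
            a.append(v1)
            b.append(v2)
    return np.asarray(a), np.asarray(b)


def pair_correlation(table: pd.DataFrame, pairs, assay: str = "rna",
                     pseudocount: float = 0.0) -> tuple[float, int]:
    """Pearson r of log10 abundances across ORF pairs; returns (r, n used)."""
    if assay not in ("rna", "ribo"):
        raise ValueError(f"unknown assay {assay!r}")
    a, b = _paired_values(table, pairs, assay, pseudocount)
    if a.size < 3:
        raise ValueError(f"only {a.size} usable pairs (need >= 3)")
    r = pearson(np.log10(a), np.log10(b)).statistic
    return float(r), int(a.size)


@dataclass
class OccupancyResult:
    numerator: int     # loci with ORF1 ribo strictly greater than ORF2 ribo
    denominator: int
    fraction: float


def occupancy_comparison(table: pd.DataFrame, pairs) -> OccupancyResult:
    """Fraction of bicistron loci with ORF1 ribo > ORF2 ribo (ties count as
    not-greater)."""
    num = den = 0
    for id1, id2 in pairs:
        if id1 not in table.index or id2 not in table.index:
            continue
        r1, r2 = float(table.at[id1, "ribo"]), float(table.at[id2, "ribo"])
        if not (np.isfinite(r1) and np.isfinite(r2)):
            continue
        den += 1
        if r1 > r2:
            num += 1
    if den == 0:
        raise ValueError("no usable pairs")
    return OccupancyResult(num, den, num / den)


@dataclass
class FootprintCorrelation:
    pearson_r: float
    spearman_rho: float
    n: int
    sign: int   # sign of the Pearson correlation


def kozak_vs_footprint(profiles, table: pd.DataFrame, pairs: dict
                       ) -> FootprintCorrelation:
    """Correlation between upstream Kozak strength and log(ORF2/ORF1 ribo).

    ``profiles`` is an iterable of (locus_id, LocusKozakProfile); ``pairs``
    maps locus_id -> (orf1_id, orf2_id).  Strength is the max bit score over
    the ORF1 start and all internal upstream sites.  Loci with zero or
    missing ribo values are excluded pairwise.
    """
    xs, ys = [], []
    for locus_id, prof in profiles:
        if locus_id not in pairs:
            continue
        id1, id2 = pairs[locus_id]
        strength = prof.max_upstream_score
        if strength is None or id1 not in table.index or id2 not in table.index:
            continue
        r1, r2 = float(table.at[id1, "ribo"]), float(table.at[id2, "ribo"])
        if r1 <= 0 or r2 <= 0:
            continue
        xs.append(strength)
        ys.append(np.log10(r2 / r1))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} usable loci (need >= 3)")
    if np.std(xs) == 0:
        raise ValueError("constant Kozak strength across loci; correlation undefined")
    r = pearson(xs, ys).statistic
    rho = float(_sps.spearmanr(xs, ys).statistic)
    return FootprintCorrelation(float(r), rho, len(xs), int(np.sign(r)))
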