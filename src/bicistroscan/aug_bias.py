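"""Observed vs composition-adjusted expected AUG 3-mer statistics per region.

Expectation is the mononucleotide-product model: for a sequence of length L
with base probabilities (pA, pC, pG, pT), the expected number of overlapping
ATG windows is ``(L - 2) * pA * pT * pG``.  Observed counts use the same
overlapping-window convention, keeping o/e internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .stats_core import pearson

__all__ = [
    "CompositionModel",
    "RegionBiasRecord",
    "count_aug",
    "base_composition",
    "expected_aug",
    "region_bias_table",
    "BICISTRONIC_CLASSES",
    "MONO_CLASSES",
]

BICISTRONIC_CLASSES = ("five_prime_utr", "orf1", "inter_orf", "before_orf2", "orf2")
MONO_CLASSES = ("mono_utr", "mono_orf", "mono_sum")


@dataclass
class CompositionModel:
    """Base probabilities under a scope: one tuple per region class
    (``per_class_pooled``) or estimated per sequence (``per_sequence``)."""

    scope: str = "per_class_pooled"
    probs: dict[str, tuple[float, float, float, float]] | None = None

    def for_sequence(self, region_class: str, seq: str):
        if self.scope == "per_sequence":
            return base_composition([seq])
        return self.probs[region_class]


@dataclass
class RegionBiasRecord:
    locus_id: str
    region_class: str
    length: int
    observed: int
    expected: float
    oe: Optional[float]


def count_aug(seq: str) -> int:
    """Number of overlapping windows equal to ATG (windows with N skipped)."""
    n = 0
    for i in range(len(seq) - 2):
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            n += 1
    return n


def base_composition(seqs: Iterable[str]) -> tuple[float, float, float, float]:
    """(pA, pC, pG, pT) pooled over sequences, ignoring N."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for s in seqs:
        for b in "ACGT":
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        return (0.25, 0.25, 0.25, 0.25)
    return tuple(counts[b] / total for b in "ACGT")  # type: ignore[return-value]


def expected_aug(length: int, comp) -> float:
    """Expected overlapping-ATG count: ``(L - 2) * pA * pT * pG`` (0 if L < 3)."""
    if length < 3:
        return 0.0
    pa, _pc, pg, pt = comp
    return (length - 2) * pa * pt * pg


def _region_class_seqs(loci) -> list[tuple[str, str, str]]:
    """Flatten loci into (locus_id, region_class, sequence) rows."""
    rows = []
    for locus_id, rs in loci:
        if rs.is_bicistronic:
            before = rs.five_prime_utr.seq + rs.orf1.seq + rs.inter_orf.seq
            rows += [
                (locus_id, "five_prime_utr", rs.five_prime_utr.seq),
                (locus_id, "orf1", rs.orf1.seq),
                (locus_id, "inter_orf", rs.inter_orf.seq),
                (locus_id, "before_orf2", before),
                (locus_id, "orf2", rs.orf2.seq),
            ]
        else:
            rows += [
                (locus_id, "mono_utr", rs.five_prime_utr.seq),
                (locus_id, "mono_orf", rs.orf1.seq),
                (locus_id, "mono_sum", rs.five_prime_utr.seq + rs.orf1.seq),
            ]
    return rows


def region_bias_table(loci, comp_scope: str = "per_class_pooled"):
    """Per-locus, per-region AUG bias records plus summary statistics.

    Parameters
    ----------
    loci : iterable of (locus_id, RegionSet)
    comp_scope : "per_class_pooled" (composition pooled over each region
        class) or "per_sequence".

    Returns
    -------
    (records, medians, pearson_r) where ``records`` is a list of
    :class:`RegionBiasRecord`, ``medians`` maps region class to the median
    o/e over loci with a defined ratio, and ``pearson_r`` is the Pearson
    correlation between (5'UTR + ORF) length and observed ATG count over
    monocistronic loci (None when fewer than 3).
    """
    loci = list(loci)
    rows = _region_class_seqs(loci)

    comp_model = CompositionModel(scope=comp_scope)
    if comp_scope == "per_class_pooled":
        pooled: dict[str, list[str]] = {}
        for _lid, cls, seq in rows:
            pooled.setdefault(cls, []).append(seq)
        comp_model.probs = {cls: base_composition(seqs) for cls, seqs in pooled.items()}
    elif comp_scope != "per_sequence":
        raise ValueError(f"unknown composition scope {comp_scope!r}")

    records = []
    for lid, cls, seq in rows:
        length = len(seq)
        obs = count_aug(seq)
        exp = expected_aug(length, comp_model.for_sequence(cls, seq))
        oe = obs / exp if (length >= 3 and exp > 0) else None
        records.append(RegionBiasRecord(lid, cls, length, obs, exp, oe))

    medians: dict[str, float | None] = {}
    for cls in BICISTRONIC_CLASSES + MONO_CLASSES:
        vals = [r.oe for r in records if r.region_class == cls and r.oe is not None]
        medians[cls] = float(np.median(vals)) if vals else None

    mono_sum = [r for r in records if r.region_class == "mono_sum"]
    pearson_r = None
    if len(mono_sum) >= 3:
        lengths = [r.length for r in mono_sum]
        counts = [r.observed for r in mono_sum]
        if np.std(lengths) > 0 and np.std(counts) > 0:
            pearson_r = pearson(lengths, counts).statistic
    return records, medians, pearson_r


def records_to_frame(records: list[RegionBiasRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.locus_id, r.region_class, r.length, r.observed, r.expected, r.oe)
         for r in records],
        columns=["locus_id", "region_class", "length", "observed", "expected", "oe"],
    )
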