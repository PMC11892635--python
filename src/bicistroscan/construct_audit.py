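"""Audit synthetic bicistronic constructs against leaky-scanning design rules.

Rules (defaults configurable):
  R1  5'UTR longer than the reference percentile threshold
  R2  ORF1 start-site score above the "suboptimal" percentile band
  R3  any ATG upstream of ORF2 besides the ORF1 start
  R4  ORF2 start-site score below the "strong" percentile band
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import percentileofscore

from .aug_bias import count_aug
from .kozak_model import (BASES, FLANK_INDICES, WINDOW, KozakPWM, bit_score,
                          start_site_window)

__all__ = [
    "RuleThresholds",
    "ReferenceDistributions",
    "AuditReport",
    "audit_construct",
    "tune_kozak",
    "suggest_aug_removal",
    "TuneResult",
    "AugRemovalSuggestion",
]

RULE_SET_VERSION = "1"

UPSTREAM_FLANK_INDICES = (0, 1, 2, 3, 4)   # -5..-1; default mutable positions


@dataclass
class RuleThresholds:
    max_utr_percentile: float = 50.0
    orf1_max_percentile: float = 40.0   # "suboptimal" band: at or below this
    orf2_min_percentile: float = 60.0   # "strong" band: at or above this


@dataclass
class ReferenceDistributions:
    """Reference monocistronic 5'UTR lengths and start-site bit scores."""

    utr_lengths: np.ndarray
    mono_scores: np.ndarray


@dataclass
class AuditReport:
    utr_length: int
    utr_percentile: float
    orf1_score: Optional[float]
    orf1_percentile: Optional[float]
    orf2_score: Optional[float]
    orf2_percentile: Optional[float]
    upstream_aug_inventory: list[tuple[int, str, int, Optional[float]]]
    flags: list[str]
    rule_set_version: str = RULE_SET_VERSION

    def to_dict(self) -> dict:
        return {
            "utr_length": self.utr_length,
            "utr_percentile": self.utr_percentile,
            "orf1_score": self.orf1_score,
            "orf1_percentile": self.orf1_percentile,
            "orf2_score": self.orf2_score,
            "orf2_percentile": self.orf2_percentile,
            "upstream_aug_inventory": [
                list(t) for t in self.upstream_aug_inventory
            ],
            "flags": list(self.flags),
            "rule_set_version": self.rule_set_version,
        }


def _pct(value: float, reference: np.ndarray) -> float:
    return float(percentileofscore(reference, value, kind="mean"))


def audit_construct(seq: str, orf1: tuple[int, int], orf2: tuple[int, int],
                    pwm: KozakPWM, refs: ReferenceDistributions,
                    thresholds: RuleThresholds | None = None) -> AuditReport:
    """Audit an mRNA construct; ``orf1``/``orf2`` are 0-based half-open
    intervals in construct coordinates (ORF1 upstream of ORF2)."""
    thresholds = thresholds or RuleThresholds()
    s1, e1 = orf1
    s2, e2 = orf2
    if not (0 <= s1 < e1 <= s2 < e2 <= len(seq)):
        raise ValueError("invalid or overlapping ORF boundaries")
    if seq[s1 : s1 + 3] != "ATG" or seq[s2 : s2 + 3] != "ATG":
        raise ValueError("ORF boundary does not start with ATG")

    utr_len = s1
    utr_pct = _pct(utr_len, refs.utr_lengths)
    score1 = bit_score(start_site_window(seq, s1), pwm)
    score2 = bit_score(start_site_window(seq, s2), pwm)
    pct1 = _pct(score1, refs.mono_scores) if score1 is not None else None
    pct2 = _pct(score2, refs.mono_scores) if score2 is not None else None

    inventory = []
    for p in range(0, s2 - 2):
        if seq[p : p + 3] == "ATG" and p != s1:
            region = ("five_prime_utr" if p < s1
                      else "orf1" if p < e1 else "inter_orf")
            inventory.append(
                (p, region, (p - s1) % 3, bit_score(start_site_window(seq, p), pwm))
            )

    flags = []
    if utr_pct > thresholds.max_utr_percentile:
        flags.append("R1_long_5utr")
    if pct1 is not None and pct1 > thresholds.orf1_max_percentile:
        flags.append("R2_orf1_not_suboptimal")
    if inventory:
        flags.append("R3_upstream_aug_present")
    if pct2 is not None and pct2 < thresholds.orf2_min_percentile:
        flags.append("R4_orf2_not_strong")
    return AuditReport(utr_len, utr_pct, score1, pct1, score2, pct2,
                       inventory, flags)


@dataclass
class TuneResult:
    variants: list[tuple[str, float]]
    note: Optional[str] = None


def tune_kozak(site: str, pwm: KozakPWM, direction: str,
               mutable_positions: tuple[int, ...] | None = None,
               max_edits: int = 1,
               target_score: float | None = None) -> TuneResult:
    """Exhaustively enumerate substitution variants of a 13-mer site.

    Only variants whose score strictly moves in ``direction`` are returned,
    sorted by |score - target| (target defaults to 0 when weakening, 2 when
    strengthening).  Default mutable positions are the upstream flank only
    (-5..-1), matching the constraint of leaving the ORF1 protein untouched.
    """
    if direction not in ("weaken", "strengthen"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(site) != WINDOW:
        raise ValueError("site must be a 13-mer")
    mutable = tuple(mutable_positions) if mutable_positions is not None \
        else UPSTREAM_FLANK_INDICES
    if not set(mutable) <= set(FLANK_INDICES):
        raise ValueError("mutable positions must be flanking positions")
    if target_score is None:
        target_score = 0.0 if direction == "weaken" else 2.0
    base_score = bit_score(site, pwm)
    if base_score is None:
        raise ValueError("input site score is undefined")

    variants = []
    seen = set()
    for k in range(1, max_edits + 1):
        for positions in itertools.combinations(mutable, k):
            for bases in itertools.product(BASES, repeat=k):
                if any(site[p] == b for p, b in zip(positions, bases)):
                    continue
                chars = list(site)
                for p, b in zip(positions, bases):
                    chars[p] = b
                variant = "".join(chars)
                if variant in seen:
                    continue
                seen.add(variant)
                score = bit_score(variant, pwm)
                if score is None:
                    continue
                if (direction == "weaken" and score < base_score) or \
                        (direction == "strengthen" and score > base_score):
                    variants.append((variant, score))
    variants.sort(key=lambda vs: (abs(vs[1] - target_score), vs[0]))
    if not variants:
        return TuneResult([], note=f"no variant can {direction} the site "
                                   "(already at the extremum)")
    return TuneResult(variants)


# ---------------------------------------------------------------------------
# AUG removal
# ---------------------------------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _synonyms() -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in _STANDARD.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(_STANDARD.stop_codons)
    syn = {}
    for codons in by_aa.values():
        for c in codons:
            syn[c] = sorted(set(codons) - {c})
    return syn


SYNONYMOUS_CODONS = _synonyms()


@dataclass
class AugRemovalSuggestion:
    position: int              # 0-based position of the ATG 3-mer in the ORF
    frame: int                 # relative to the ORF reading frame
    codon_index: Optional[int]
    edit: Optional[tuple[str, str]]
    consequence: str           # nonsynonymous | synonymous | unresolvable
    sequence: Optional[str]    # full ORF sequence after the edit


def suggest_aug_removal(orf_seq: str) -> list[AugRemovalSuggestion]:
    """Suggest edits removing every ATG 3-mer beyond the initiator.

    In-frame internal ATG codons get a Met->Leu (CTG) replacement flagged as
    protein-changing.  Out-of-frame ATGs get a synonymous substitution of an
    overlapping codon found by brute force over the codon table; if no
    synonymous codon destroys the ATG without creating a new one, the site
    is reported unresolvable.
    """
    if len(orf_seq) % 3 != 0:
        raise ValueError("ORF length must be divisible by 3")
    n_before = count_aug(orf_seq)
    out = []
    for p in range(len(orf_seq) - 2):
        if orf_seq[p : p + 3] != "ATG":
            continue
        if p == 0:
            continue  # initiator
        frame = p % 3
        if frame == 0:
            ci = p // 3
            edited = orf_seq[:p] + "CTG" + orf_seq[p + 3 :]
            out.append(AugRemovalSuggestion(p, 0, ci, ("ATG", "CTG"),
                                            "nonsynonymous", edited))
            continue
        # out-of-frame: try synonymous replacement of each overlapping codon
        candidates = sorted({p // 3, (p + 2) // 3})
        resolved = False
        for ci in candidates:
            if ci == 0:
                continue  # never touch the initiator codon
            old = orf_seq[3 * ci : 3 * ci + 3]
            for alt in SYNONYMOUS_CODONS.get(old, []):
                edited = orf_seq[: 3 * ci] + alt + orf_seq[3 * ci + 3 :]
                if edited[p : p + 3] != "ATG" and count_aug(edited) < n_before:
                    out.append(AugRemovalSuggestion(p, frame, ci, (old, alt),
                                                    "synonymous", edited))
                    resolved = True
                    break
            if resolved:
                break
        if not resolved:
            out.append(AugRemovalSuggestion(p, frame, None, None,
                                            "unresolvable", None))
    return out
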