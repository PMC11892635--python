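"""Kozak-context PWM: training, information content, and bit scoring.

The initiation-site window is 13 nt: five flanking bases on each side of the
invariant ATG (upstream offsets -5..-1, the ATG at +1..+3, downstream
+4..+8).  The three ATG positions are excluded from scoring, so a site score
is the mean per-position letter height ``p_i(x_i) * R_i`` over the 10
flanking positions, on a [0, 2]-bit scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WINDOW",
    "FLANK_INDICES",
    "CORE_INDICES",
    "WINDOW_OFFSETS",
    "KozakPWM",
    "LocusKozakProfile",
    "build_pwm",
    "bit_score",
    "locus_kozak_profile",
    "start_site_window",
    "start_site_score",
    "split_train_eval",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

WINDOW = 13
CORE_INDICES = (5, 6, 7)          # the invariant ATG
FLANK_INDICES = (0, 1, 2, 3, 4, 8, 9, 10, 11, 12)
WINDOW_OFFSETS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5, 6, 7, 8)
_MAX_UNSCORABLE = 3               # >3 missing flank positions -> score missing


@dataclass
class KozakPWM:
    """Per-position base probabilities and information content (bits).

    ``probs`` has shape (13, 4) in base order ACGT; ``info`` is the
    per-position information content ``R_i = 2 + sum_b p log2 p``.
    """

    probs: np.ndarray
    info: np.ndarray
    n_sites: int
    pseudocount: float
    window_offsets: tuple[int, ...] = WINDOW_OFFSETS

    def consensus(self) -> str:
        """Per-position argmax site (ATG fixed at the core)."""
        letters = [BASES[i] for i in self.probs.argmax(axis=1)]
        for i, b in zip(CORE_INDICES, "ATG"):
            letters[i] = b
        return "".join(letters)

    def max_score(self) -> float:
        """Bit score of the consensus site (the attainable maximum)."""
        return bit_score(self.consensus(), self)

    def sample_sites(self, n: int, rng: np.random.Generator) -> list[str]:
        """Draw n sites from the per-position distributions (ATG core fixed)."""
        cols = []
        for i in range(WINDOW):
            if i in CORE_INDICES:
                cols.append(np.full(n, "ATG"[CORE_INDICES.index(i)]))
            else:
                idx = rng.choice(4, size=n, p=self.probs[i])
                cols.append(np.array(list(BASES))[idx])
        return ["".join(row) for row in zip(*cols)]

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "window_offsets": list(self.window_offsets),
                "probs": self.probs.tolist(),
                "info": self.info.tolist(),
                "n_sites": self.n_sites,
                "pseudocount": self.pseudocount,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "KozakPWM":
        d = json.loads(text)
        return cls(
            probs=np.asarray(d["probs"], dtype=float),
            info=np.asarray(d["info"], dtype=float),
            n_sites=int(d["n_sites"]),
            pseudocount=float(d["pseudocount"]),
            window_offsets=tuple(d["window_offsets"]),
        )


@dataclass
class LocusKozakProfile:
    """Start-site scores for one bicistronic locus."""

    transcript_id: str
    orf1_score: float | None
    orf2_score: float | None
    internal_sites: list[tuple[int, int, float | None]] = field(default_factory=list)

    @property
    def ratio(self) -> float | None:
        if self.orf1_score is None or self.orf2_score is None or self.orf2_score <= 0:
            return None
        return self.orf1_score / self.orf2_score

    @property
    def max_upstream_score(self) -> float | None:
        """Max score over the ORF1 start and all internal sites (leak gate)."""
        scores = [self.orf1_score] + [s for _, _, s in self.internal_sites]
        scores = [s for s in scores if s is not None]
        return max(scores) if scores else None


def _info_from_probs(probs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=1)


def build_pwm(sites: list[str], pseudocount: float = 0.5) -> KozakPWM:
    """Build a :class:`KozakPWM` from 13-mer training sites.

    Each site must be a clean 13-mer with ATG at positions 6-8 and no N
    (sites with incomplete upstream context are excluded by the caller).
    ``probs = (count + pseudocount) / (n + 4 * pseudocount)`` per column.
    """
    if not sites:
        raise ValueError("empty site list")
    counts = np.zeros((WINDOW, 4), dtype=float)
    for idx, site in enumerate(sites):
        if len(site) != WINDOW:
            raise ValueError(f"site {idx}: length {len(site)} != {WINDOW}")
        if site[5:8] != "ATG":
            raise ValueError(f"site {idx}: core {site[5:8]!r} is not ATG")
        for i, b in enumerate(site):
            j = _BASE_INDEX.get(b)
            if j is None:
                raise ValueError(f"site {idx}: invalid base {b!r} at position {i}")
            counts[i, j] += 1.0
    n = float(len(sites))
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return KozakPWM(
        probs=probs,
        info=_info_from_probs(probs),
        n_sites=len(sites),
        pseudocount=pseudocount,
    )


def bit_score(site: str, pwm: KozakPWM) -> float | None:
    """Mean letter height ``p_i(x_i) * R_i`` over the 10 flanking positions.

    Positions holding N (or any non-ACGT character, e.g. padding for a
    truncated window) are skipped and the mean renormalized over the scored
    positions; more than 3 unscorable flanks gives a missing score (None).
    """
    if len(site) != WINDOW:
        raise ValueError(f"site length {len(site)} != {WINDOW}")
    heights = []
    unscorable = 0
    for i in FLANK_INDICES:
        j = _BASE_INDEX.get(site[i])
        if j is None:
            unscorable += 1
        else:
            heights.append(pwm.probs[i, j] * pwm.info[i])
    if unscorable > _MAX_UNSCORABLE:
        return None
    return float(np.mean(heights))


def start_site_window(mrna: str, start: int) -> str:
    """Cut the 13-nt window around an ATG at ``start``, N-padding the ends."""
    left = start - 5
    right = start + 8
    pad_l = max(0, -left)
    pad_r = max(0, right - len(mrna))
    return "N" * pad_l + mrna[max(0, left) : min(len(mrna), right)] + "N" * pad_r


def start_site_score(regions, pwm: KozakPWM) -> float | None:
    """Bit score of a RegionSet's ORF1 (main ORF) start site."""
    return bit_score(start_site_window(regions.mrna, regions.orf1.start), pwm)


def locus_kozak_profile(regions, pwm: KozakPWM) -> LocusKozakProfile:
    """Score ORF1/ORF2 start sites of a bicistronic locus and enumerate
    internal ATGs (any frame) in 5'UTR + ORF1 + inter-ORF, excluding the
    annotated ORF1 start."""
    if not regions.is_bicistronic:
        raise ValueError(f"{regions.transcript_id}: not bicistronic")
    mrna = regions.mrna
    s1 = regions.orf1.start
    s2 = regions.orf2.start
    internal = []
    for p in range(0, s2 - 2):
        if mrna[p : p + 3] == "ATG" and p != s1:
            internal.append((p, (p - s1) % 3, bit_score(start_site_window(mrna, p), pwm)))
    return LocusKozakProfile(
        transcript_id=regions.transcript_id,
        orf1_score=bit_score(start_site_window(mrna, s1), pwm),
        orf2_score=bit_score(start_site_window(mrna, s2), pwm),
        internal_sites=internal,
    )


def split_train_eval(ids: list[str], seed: int) -> tuple[list[str], list[str]]:
    """Random disjoint halves (odd n: the extra id goes to eval)."""
    if len(ids) < 2:
        raise ValueError("need at least 2 ids to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    k = len(ids) // 2
    train = [ids[i] for i in sorted(order[:k])]
    ev = [ids[i] for i in sorted(order[k:])]
    return train, ev
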