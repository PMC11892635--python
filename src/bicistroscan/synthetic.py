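"""Synthetic genome / expression / homology generator with a truth table.

Every generated world is a pure function of its :class:`SimSpec` (the seed
lives in the spec).  Default parameters make the synthetic world resemble
the length, Kozak-ratio, AUG-depletion, and expression-correlation structure
that the analysis modules are designed to measure, and the truth table
records the planted values so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import transcript_io as tio
from .aug_bias import count_aug
from .kozak_model import BASES, KozakPWM, bit_score, start_site_window
from .transcript_io import GenomeSequences, TranscriptModel, revcomp

__all__ = [
    "LengthDist",
    "KozakSimSpec",
    "ExpressionSimSpec",
    "HomologySimSpec",
    "SimSpec",
    "SimWorld",
    "HomologyWorld",
    "simulate_genome",
    "simulate_expression",
    "simulate_homology",
    "write_world",
    "write_homology",
]

_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------


@dataclass
class LengthDist:
    """Log-normal length distribution parameterized by its median (nt)."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return np.exp(rng.normal(math.log(self.median), self.sigma, size=n))


@dataclass
class KozakSimSpec:
    """Initiation-site context model for the generator.

    ``favored_flanks`` are the preferred bases at the 10 flanking positions
    (5 upstream + 5 downstream); each holds probability ``strength`` with
    the remainder spread over the other bases by genome composition.
    ``ratio_median``/``ratio_sigma`` parameterize the planted per-locus
    ORF1:ORF2 score ratio (log-normal); ``orf2_band`` is the percentile band
    of the score distribution from which ORF2 sites are drawn.
    """

    favored_flanks: str = "GCCACGCGCC"
    strength: float = 0.75
    orf2_band: tuple[float, float] = (40.0, 90.0)
    ratio_median: float = 0.79
    ratio_sigma: float = 0.10


@dataclass
class ExpressionSimSpec:
    log_mu: float = 2.0          # mean of log10 RNA abundance
    log_sd: float = 0.6
    rna_r: float = 0.92          # planted ORF1-ORF2 log-scale RNA correlation
    ribo_k: float = 3.0          # leak = exp(-k * upstream Kozak strength)
    ribo_noise_sd: float = 0.15  # log10 sd of the ORF2 attenuation noise
    te_noise_sd: float = 0.20    # log10 sd of RNA -> ribo transfer noise


@dataclass
class HomologySimSpec:
    colinear_fraction: float = 0.6
    n_decoy: int = 20
    isoseq_fraction: float = 0.5
    est_fraction: float = 0.3


@dataclass
class SimSpec:
    """Full parameterization of one synthetic species."""

    seed: int = 0
    species: str = "simsp"
    n_mono: int = 200
    n_bicistron: int = 36
    n_mixed: int = 0
    composition: tuple[float, float, float, float] = (0.18, 0.32, 0.32, 0.18)
    lengths: dict[str, LengthDist] = field(default_factory=lambda: {
        "utr5_bi": LengthDist(83, 0.25),
        "orf1": LengthDist(357, 0.25),
        "inter_orf": LengthDist(183, 0.35),
        "orf2": LengthDist(1113, 0.25),
        "utr5_mono": LengthDist(214, 0.40),
        "mono_orf": LengthDist(1509, 0.35),
        "utr3": LengthDist(200, 0.30),
    })
    aug_oe_targets: dict[str, float] = field(default_factory=lambda: {
        "before_orf2": 0.49,
        "mono_utr": 0.47,
    })
    kozak: KozakSimSpec = field(default_factory=KozakSimSpec)
    expression: ExpressionSimSpec = field(default_factory=ExpressionSimSpec)
    homology: HomologySimSpec = field(default_factory=HomologySimSpec)
    spacer_nt: int = 2000

    # -- presets -----------------------------------------------------------

    @classmethod
    def cre_like(cls, seed: int = 0, **overrides) -> "SimSpec":
        """Chlamydomonas-like defaults (the class defaults)."""
        return cls(seed=seed, species="cre", **overrides)

    @classmethod
    def apro_like(cls, seed: int = 0, **overrides) -> "SimSpec":
        """Auxenochlorella-like defaults: shorter ORF1/inter-ORF/5'UTR and a
        slightly higher planted score ratio."""
        spec = cls(seed=seed, species="apro", **overrides)
        spec.lengths = dict(spec.lengths)
        spec.lengths.update({
            "utr5_bi": LengthDist(54, 0.25),
            "orf1": LengthDist(291, 0.25),
            "inter_orf": LengthDist(40, 0.35),
            "orf2": LengthDist(1185, 0.25),
            "utr5_mono": LengthDist(112, 0.40),
            "mono_orf": LengthDist(1005, 0.35),
        })
        spec.aug_oe_targets = {"before_orf2": 0.48, "mono_utr": 0.40}
        spec.kozak = KozakSimSpec(ratio_median=0.88)
        return spec

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimSpec":
        d = yaml.safe_load(text)
        d["lengths"] = {k: LengthDist(**v) for k, v in d.get("lengths", {}).items()}
        d["composition"] = tuple(d["composition"])
        kz = d.get("kozak", {})
        kz["orf2_band"] = tuple(kz.get("orf2_band", (40.0, 90.0)))
        d["kozak"] = KozakSimSpec(**kz)
        d["expression"] = ExpressionSimSpec(**d.get("expression", {}))
        d["homology"] = HomologySimSpec(**d.get("homology", {}))
        return cls(**d)

    def generating_pwm(self) -> KozakPWM:
        """The PWM the generator samples initiation-site flanks from."""
        pA, pC, pG, pT = self.composition
        comp = {"A": pA, "C": pC, "G": pG, "T": pT}
        probs = np.zeros((13, 4))
        flank_iter = iter(self.kozak.favored_flanks)
        for i in range(13):
            if i in (5, 6, 7):
                probs[i, "ACGT".index("ATG"[i - 5])] = 1.0
                continue
            fav = next(flank_iter)
            rest = {b: p for b, p in comp.items() if b != fav}
            z = sum(rest.values())
            for j, b in enumerate(BASES):
                probs[i, j] = (self.kozak.strength if b == fav
                               else (1 - self.kozak.strength) * rest[b] / z)
        with np.errstate(divide="ignore"):
            plogp = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1)), 0)
        info = 2.0 + plogp.sum(axis=1)
        return KozakPWM(probs=probs, info=info, n_sites=0, pseudocount=0.0)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


@dataclass
class SimWorld:
    spec: SimSpec
    genome: GenomeSequences
    models: list[TranscriptModel]
    truth: pd.DataFrame
    pwm: KozakPWM


def _rand_seq(rng, comp, n: int) -> list[str]:
    idx = rng.choice(4, size=n, p=comp)
    lut = np.array(list(BASES))
    return list(lut[idx])


def _pround(x: float, rng) -> int:
    lo = math.floor(x)
    return lo + (1 if rng.random() < x - lo else 0)


def _sample_flank_for_score(pwm: KozakPWM, target: float, rng,
                            n_candidates: int = 300) -> str:
    sites = pwm.sample_sites(n_candidates, rng)
    scores = np.array([bit_score(s, pwm) for s in sites])
    return sites[int(np.argmin(np.abs(scores - target)))]


def _adjust_aug_count(chars: list[str], target: int, protected: set[int],
                      rng, label: str, max_iter: int = 20000) -> None:
    """Mutate a sequence in place until its overlapping-ATG count equals
    ``target`` (best effort), never touching protected positions."""

    def positions():
        s = "".join(chars)
        return [p for p in range(len(s) - 2) if s[p : p + 3] == "ATG"]

    free3 = [p for p in range(len(chars) - 2)
             if not ({p, p + 1, p + 2} & protected)]
    for _ in range(max_iter):
        hits = positions()
        if len(hits) == target:
            return
        if len(hits) > target:
            editable = [p for p in hits if p + 1 not in protected]
            if not editable:
                return  # only protected ATGs remain; accept
            p = editable[rng.integers(len(editable))]
            new_base = "C" if rng.random() < 0.5 else "G"
            chars[p + 1] = new_base
            # composition-preserving compensation: trade the introduced base
            # back to T somewhere it cannot seed a new ATG
            cands = [q for q in range(1, len(chars) - 1)
                     if q not in protected and chars[q] == new_base
                     and q != p + 1
                     and not (chars[q - 1] == "A" and chars[q + 1] == "G")]
            if cands:
                chars[cands[rng.integers(len(cands))]] = "T"
        else:
            if not free3:
                return
            p = free3[rng.integers(len(free3))]
            chars[p], chars[p + 1], chars[p + 2] = "A", "T", "G"
    raise RuntimeError(f"AUG adjustment did not converge for {label}")


def _orf_body(rng, comp, site: str, length: int, stop: str) -> list[str]:
    """ATG + downstream flank + random fill + stop, total ``length`` nt."""
    fill = _rand_seq(rng, comp, length - 11)
    return list("ATG") + list(site[8:13]) + fill + list(stop)


class _LocusBuilder:
    """Accumulates transcript blocks onto a single pseudo-chromosome."""

    def __init__(self, spec: SimSpec, rng):
        self.spec = spec
        self.rng = rng
        self.chrom = f"{spec.species}_chr1"
        self.parts: list[str] = []
        self.cursor = 0
        self.models: list[TranscriptModel] = []

    def place(self, block: str, strand: str,
              tid: str, gene_ids: list[str],
              orf_t_intervals: list[tuple[int, int]],
              extra_isoform: Optional[tuple[str, list[str], list[tuple[int, int]]]] = None,
              ) -> None:
        spacer = "".join(_rand_seq(self.rng, self.spec.composition, self.spec.spacer_nt))
        self.parts.append(spacer)
        self.cursor += len(spacer)
        start = self.cursor
        L = len(block)
        genomic = block if strand == "+" else revcomp(block)
        self.parts.append(genomic)
        self.cursor += L

        def g_iv(ts: int, te: int) -> tuple[int, int]:
            if strand == "+":
                return (start + ts, start + te)
            return (start + L - te, start + L - ts)

        def make_model(tid_, gids_, ivs_):
            return TranscriptModel(
                transcript_id=tid_,
                gene_ids=list(gids_),
                chrom=self.chrom,
                strand=strand,
                exons=[(start, start + L)],
                orfs=[[g_iv(ts, te)] for ts, te in ivs_],
            )

        self.models.append(make_model(tid, gene_ids, orf_t_intervals))
        if extra_isoform is not None:
            tid2, gids2, ivs2 = extra_isoform
            self.models.append(make_model(tid2, gids2, ivs2))

    def finish(self) -> GenomeSequences:
        tail = "".join(_rand_seq(self.rng, self.spec.composition, self.spec.spacer_nt))
        return GenomeSequences({self.chrom: "".join(self.parts) + tail})


def _length(rng, dist: LengthDist, minimum: int, multiple3: bool = False) -> int:
    v = float(dist.sample(rng, 1)[0])
    if multiple3:
        return max(minimum, 3 * int(round(v / 3)))
    return max(minimum, int(round(v)))


def simulate_genome(spec: SimSpec) -> SimWorld:
    """Build the synthetic genome, transcript models, and truth table."""
    rng = np.random.default_rng([spec.seed, 0])
    pwm = spec.generating_pwm()
    comp = np.asarray(spec.composition)
    pA, _pC, pG, pT = spec.composition
    p_atg = pA * pT * pG

    # empirical score quantiles of the generating PWM
    ref_scores = np.sort([bit_score(s, pwm) for s in pwm.sample_sites(4000, rng)])

    def quantile(pct: float) -> float:
        return float(np.quantile(ref_scores, pct / 100.0))

    lo_b, hi_b = spec.kozak.orf2_band
    if not (0.0 <= lo_b < hi_b <= 100.0):
        raise ValueError(f"unattainable ORF2 percentile band ({lo_b}, {hi_b})")
    smin, smax = ref_scores[0], ref_scores[-1]

    builder = _LocusBuilder(spec, rng)
    truth_rows = []

    def sample_clean_site(target: Optional[float] = None) -> str:
        # resample until codon 2 of the resulting ORF would not be a stop
        for _ in range(100):
            site = (pwm.sample_sites(1, rng)[0] if target is None
                    else _sample_flank_for_score(pwm, target, rng))
            if site[8:11] not in _STOPS:
                return site
        raise RuntimeError("could not sample a stop-free initiation site")

    # interleave locus kinds deterministically
    kinds = (["mono"] * spec.n_mono + ["bi"] * spec.n_bicistron
             + ["mixed"] * spec.n_mixed)
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]
    i_mono = i_bi = i_mix = 0

    for kind in kinds:
        strand = "+" if rng.random() < 0.5 else "-"
        utr3 = _rand_seq(rng, comp, _length(rng, spec.lengths["utr3"], 20))

        if kind == "mono":
            gid = f"{spec.species}.g{i_mono:05d}"
            i_mono += 1
            site = sample_clean_site()
            L_u = _length(rng, spec.lengths["utr5_mono"], 8)
            L_o = _length(rng, spec.lengths["mono_orf"], 30, multiple3=True)
            utr5 = _rand_seq(rng, comp, L_u)
            utr5[-5:] = list(site[0:5])
            orf = _orf_body(rng, comp, site, L_o, _STOPS[rng.integers(3)])
            if "mono_utr" in spec.aug_oe_targets:
                tgt = _pround(
                    spec.aug_oe_targets["mono_utr"] * max(0, L_u - 2) * p_atg, rng)
                protected = set(range(L_u - 5, L_u))
                _adjust_aug_count(utr5, tgt, protected, rng, f"{gid}:utr5")
            block = "".join(utr5) + "".join(orf) + "".join(utr3)
            s1 = L_u
            builder.place(block, strand, f"{gid}.t1", [gid], [(s1, s1 + L_o)])
            truth_rows.append({
                "locus_id": gid, "locus_class": "monocistronic",
                "transcript_id": f"{gid}.t1", "gene1": gid, "gene2": None,
                "strand": strand, "utr5_len": L_u, "orf1_len": L_o,
                "inter_len": None, "orf2_len": None,
                "orf1_score": bit_score(site, pwm), "orf2_score": None,
                "ratio": None, "upstream_strength": None,
                "before_oe_target": None,
            })
            continue

        # bicistronic (exclusive or mixed)
        if kind == "bi":
            base = f"{spec.species}.b{i_bi:03d}"
            i_bi += 1
            cls = "bicistronic_exclusive"
        else:
            base = f"{spec.species}.x{i_bi + i_mix:03d}"
            i_mix += 1
            cls = "polycistronic_mixed"
        g1, g2 = base + "a", base + "b"

        u2 = rng.uniform(lo_b, hi_b)
        site2 = sample_clean_site(quantile(u2))
        s2_score = bit_score(site2, pwm)
        ratio = math.exp(rng.normal(math.log(spec.kozak.ratio_median),
                                    spec.kozak.ratio_sigma))
        site1 = sample_clean_site(float(np.clip(ratio * s2_score, smin, smax)))
        s1_score = bit_score(site1, pwm)

        L_u = _length(rng, spec.lengths["utr5_bi"], 8)
        L_1 = _length(rng, spec.lengths["orf1"], 18, multiple3=True)
        L_i = _length(rng, spec.lengths["inter_orf"], 8)
        L_2 = _length(rng, spec.lengths["orf2"], 30, multiple3=True)

        utr5 = _rand_seq(rng, comp, L_u)
        utr5[-5:] = list(site1[0:5])
        orf1 = _orf_body(rng, comp, site1, L_1, _STOPS[rng.integers(3)])
        inter = _rand_seq(rng, comp, L_i)
        inter[-5:] = list(site2[0:5])
        orf2 = _orf_body(rng, comp, site2, L_2, _STOPS[rng.integers(3)])

        before = utr5 + orf1 + inter
        s1_pos = L_u
        e1_pos = L_u + L_1
        protected = set(range(s1_pos - 5, s1_pos + 8))
        protected |= set(range(e1_pos - 3, e1_pos))
        protected |= set(range(len(before) - 5, len(before)))
        oe_target = spec.aug_oe_targets.get("before_orf2")
        if oe_target is not None:
            tgt = max(1, _pround(oe_target * (len(before) - 2) * p_atg, rng))
            _adjust_aug_count(before, tgt, protected, rng, f"{base}:before_orf2")
        utr5 = before[:L_u]
        orf1 = before[L_u:e1_pos]
        inter = before[e1_pos:]

        block = "".join(before) + "".join(orf2) + "".join(utr3)
        s2_pos = len(before)
        mrna = block
        internal_scores = [
            bit_score(start_site_window(mrna, p), pwm)
            for p in range(0, s2_pos - 2)
            if mrna[p : p + 3] == "ATG" and p != s1_pos
        ]
        strength = max([s1_score] + [s for s in internal_scores if s is not None])

        extra = None
        if cls == "polycistronic_mixed":
            extra = (f"{base}.t2", [g1], [(s1_pos, e1_pos)])
        builder.place(block, strand, f"{base}.t1", [g1, g2],
                      [(s1_pos, e1_pos), (s2_pos, s2_pos + L_2)],
                      extra_isoform=extra)
        truth_rows.append({
            "locus_id": base, "locus_class": cls,
            "transcript_id": f"{base}.t1", "gene1": g1, "gene2": g2,
            "strand": strand, "utr5_len": L_u, "orf1_len": L_1,
            "inter_len": L_i, "orf2_len": L_2,
            "orf1_score": s1_score, "orf2_score": s2_score,
            "ratio": s1_score / s2_score,
            "upstream_strength": strength,
            "before_oe_target": oe_target,
        })

    genome = builder.finish()
    truth = pd.DataFrame(truth_rows)
    return SimWorld(spec=spec, genome=genome, models=builder.models,
                    truth=truth, pwm=pwm)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(spec: SimSpec, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-ORF RNA/Ribo abundances with planted correlation and attenuation."""
    rng = np.random.default_rng([spec.seed, 1])
    ex = spec.expression
    rows = []
    for rec in truth.itertuples():
        if rec.locus_class == "monocistronic":
            l1 = rng.normal(ex.log_mu, ex.log_sd)
            rna = 10.0 ** l1
            ribo = rna * 10.0 ** rng.normal(0.0, ex.te_noise_sd)
            rows.append((rec.gene1, rna, ribo))
        else:
            z = rng.standard_normal()
            l1 = rng.normal(ex.log_mu, ex.log_sd)
            l2 = (ex.log_mu + ex.rna_r * (l1 - ex.log_mu)
                  + ex.log_sd * math.sqrt(1.0 - ex.rna_r ** 2) * z)
            rna1, rna2 = 10.0 ** l1, 10.0 ** l2
            ribo1 = rna1 * 10.0 ** rng.normal(0.0, ex.te_noise_sd)
            leak = math.exp(-ex.ribo_k * float(rec.upstream_strength))
            ribo2 = ribo1 * leak * 10.0 ** rng.normal(0.0, ex.ribo_noise_sd)
            rows.append((rec.gene1, rna1, ribo1))
            rows.append((rec.gene2, rna2, ribo2))
    return pd.DataFrame(rows, columns=["orf_id", "rna", "ribo"])


# ---------------------------------------------------------------------------
# Homology simulation
# ---------------------------------------------------------------------------


@dataclass
class HomologyWorld:
    q2t: pd.DataFrame
    t2q: pd.DataFrame
    target_genes: dict
    evidence: dict[str, dict[str, bool]]
    colinear_truth: dict[str, str]   # locus_id -> expected status tier


def _hit_row(q: str, t: str, bitscore: float, evalue: float = 1e-40) -> list:
    return [q, t, 85.0, 120, 10, 1, 1, 120, 1, 120, evalue, bitscore]


def simulate_homology(spec: SimSpec, truth: pd.DataFrame) -> HomologyWorld:
    """Hit tables and a target annotation with a planted colinear subset.

    Exactly ``floor(colinear_fraction * n_bicistron)`` loci are colinear in
    the target; the rest cycle through opposite-strand, intervening-gene,
    and missing-ortholog failure modes.  Reciprocal-best structure is
    guaranteed for planted pairs; decoy hits always score lower.
    """
    from .conservation import HIT_COLUMNS, GeneInterval

    rng = np.random.default_rng([spec.seed, 2])
    bic = truth[truth["locus_class"] == "bicistronic_exclusive"].reset_index(drop=True)
    n = len(bic)
    k = int(math.floor(spec.homology.colinear_fraction * n))
    colinear_idx = set(rng.choice(n, size=k, replace=False).tolist())

    chrom = "tgt_chr1"
    cursor = 1000
    genes: dict[str, GeneInterval] = {}
    q2t_rows, t2q_rows = [], []
    evidence: dict[str, dict[str, bool]] = {}
    colinear_truth: dict[str, str] = {}
    fail_mode = 0
    all_targets = []

    for i, rec in enumerate(bic.itertuples()):
        tA, tB = f"tgt_{i:03d}A", f"tgt_{i:03d}B"
        bs = 300.0 + rng.random() * 50
        if i in colinear_idx:
            strand = "+" if rng.random() < 0.5 else "-"
            genes[tA] = GeneInterval(tA, chrom, strand, cursor, cursor + 600)
            genes[tB] = GeneInterval(tB, chrom, strand, cursor + 900, cursor + 1500)
            cursor += 2600
            q2t_rows += [_hit_row(rec.gene1, tA, bs), _hit_row(rec.gene2, tB, bs)]
            t2q_rows += [_hit_row(tA, rec.gene1, bs), _hit_row(tB, rec.gene2, bs)]
            iso = rng.random() < spec.homology.isoseq_fraction
            est = (not iso) and rng.random() < spec.homology.est_fraction
            evidence[rec.locus_id] = {"isoseq": bool(iso), "est": bool(est)}
            colinear_truth[rec.locus_id] = (
                "colinear+isoseq" if iso else "colinear+est" if est else "colinear")
            all_targets += [tA, tB]
        else:
            colinear_truth[rec.locus_id] = "none"
            mode = fail_mode % 3
            fail_mode += 1
            if mode == 0:      # opposite strands
                genes[tA] = GeneInterval(tA, chrom, "+", cursor, cursor + 600)
                genes[tB] = GeneInterval(tB, chrom, "-", cursor + 900, cursor + 1500)
                cursor += 2600
                q2t_rows += [_hit_row(rec.gene1, tA, bs), _hit_row(rec.gene2, tB, bs)]
                t2q_rows += [_hit_row(tA, rec.gene1, bs), _hit_row(tB, rec.gene2, bs)]
                all_targets += [tA, tB]
            elif mode == 1:    # same strand with an intervening gene
                tX = f"tgt_{i:03d}X"
                genes[tA] = GeneInterval(tA, chrom, "+", cursor, cursor + 600)
                genes[tX] = GeneInterval(tX, chrom, "+", cursor + 700, cursor + 850)
                genes[tB] = GeneInterval(tB, chrom, "+", cursor + 900, cursor + 1500)
                cursor += 2600
                q2t_rows += [_hit_row(rec.gene1, tA, bs), _hit_row(rec.gene2, tB, bs)]
                t2q_rows += [_hit_row(tA, rec.gene1, bs), _hit_row(tB, rec.gene2, bs)]
                all_targets += [tA, tB, tX]
            else:              # ORF2 ortholog missing
                genes[tA] = GeneInterval(tA, chrom, "+", cursor, cursor + 600)
                cursor += 1500
                q2t_rows += [_hit_row(rec.gene1, tA, bs)]
                t2q_rows += [_hit_row(tA, rec.gene1, bs)]
                all_targets += [tA]

    # decoy filler genes and strictly-lower-scoring decoy hits
    for d in range(spec.homology.n_decoy):
        tD = f"tgt_dec{d:03d}"
        genes[tD] = GeneInterval(tD, chrom, "+", cursor, cursor + 400)
        cursor += 1200
        all_targets.append(tD)
    for rec in bic.itertuples():
        if rng.random() < 0.5 and all_targets:
            tD = all_targets[rng.integers(len(all_targets))]
            q2t_rows.append(_hit_row(rec.gene1, tD, 80.0 + rng.random() * 20, 1e-8))

    q2t = pd.DataFrame(q2t_rows, columns=HIT_COLUMNS)
    t2q = pd.DataFrame(t2q_rows, columns=HIT_COLUMNS)
    return HomologyWorld(q2t, t2q, genes, evidence, colinear_truth)


# ---------------------------------------------------------------------------
# Writers (text formats only)
# ---------------------------------------------------------------------------


def write_world(world: SimWorld, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    tio.write_genome(world.genome, os.path.join(outdir, "genome.fa"))
    tio.write_annotation(world.models, os.path.join(outdir, "annotation.gff3"))
    world.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "pwm.json"), "w") as fh:
        fh.write(world.pwm.to_json())


def write_homology(hom: HomologyWorld, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    hom.q2t.to_csv(os.path.join(outdir, "hits_q2t.tsv"), sep="\t",
                   index=False, header=False)
    hom.t2q.to_csv(os.path.join(outdir, "hits_t2q.tsv"), sep="\t",
                   index=False, header=False)
    with open(os.path.join(outdir, "target.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in hom.target_genes.values():
            fh.write("\t".join([g.chrom, "sim", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", f"ID={g.gene_id}"])
                     + "\n")
    ev = pd.DataFrame(
        [(lid, int(f.get("isoseq", False)), int(f.get("est", False)))
         for lid, f in hom.evidence.items()],
        columns=["locus_id", "isoseq", "est"],
    )
    ev.to_csv(os.path.join(outdir, "evidence.tsv"), sep="\t", index=False)
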