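"""Locus classification (mono / exclusively bicistronic / mixed), uORF
discovery, and structural length statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .transcript_io import GenomeSequences, RegionSet, TranscriptModel, extract_regions

__all__ = [
    "LocusClassification",
    "StructuralStats",
    "classify_loci",
    "find_uorfs",
    "structural_stats",
    "colinear_mono_pairs",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_MIN_UORF_NT = 9          # start + >=1 codon + stop
DEFAULT_COLINEAR_MAX_NT = 20_000


@dataclass
class LocusClassification:
    locus_id: str
    gene_ids: tuple[str, ...]
    locus_class: str              # monocistronic | bicistronic_exclusive | polycistronic_mixed
    n_transcripts: int
    orf_count_per_transcript: list[int]
    transcript_ids: list[str] = field(default_factory=list)
    flagged: bool = False         # set for >2-ORF transcripts (tricistrons etc.)


def _group_loci(models: list[TranscriptModel]) -> list[list[TranscriptModel]]:
    """Union transcripts sharing any gene id into loci."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for m in models:
        for g in m.gene_ids:
            parent.setdefault(g, g)
        for g in m.gene_ids[1:]:
            union(m.gene_ids[0], g)
    groups: dict[str, list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault(find(m.gene_ids[0]), []).append(m)
    return [groups[k] for k in sorted(groups)]


def classify_loci(models: list[TranscriptModel]) -> list[LocusClassification]:
    """One deterministic classification per locus (transcripts grouped by
    shared gene ids).

    ``bicistronic_exclusive`` requires every transcript of the locus to carry
    the same two ORFs; a locus mixing one- and two-ORF isoforms (or carrying
    any >2-ORF transcript) is ``polycistronic_mixed``.
    """
    out = []
    for transcripts in _group_loci(models):
        gene_sets = [tuple(m.gene_ids) for m in transcripts]
        orf_counts = [m.n_orfs for m in transcripts]
        all_genes = tuple(sorted({g for gs in gene_sets for g in gs}))
        locus_id = "|".join(all_genes)
        flagged = any(c > 2 for c in orf_counts)
        if all(c == 1 for c in orf_counts):
            cls = "monocistronic"
        elif (not flagged
              and all(c == 2 for c in orf_counts)
              and len({frozenset(gs) for gs in gene_sets}) == 1):
            cls = "bicistronic_exclusive"
        else:
            cls = "polycistronic_mixed"
        out.append(
            LocusClassification(
                locus_id=locus_id,
                gene_ids=all_genes,
                locus_class=cls,
                n_transcripts=len(transcripts),
                orf_count_per_transcript=orf_counts,
                transcript_ids=[m.transcript_id for m in transcripts],
                flagged=flagged,
            )
        )
    return out


def find_uorfs(regions: RegionSet, min_coding_nt: int = DEFAULT_MIN_UORF_NT
               ) -> list[tuple[int, int, int]]:
    """Upstream ORFs fully contained in the 5'UTR.

    Each uORF runs from an ATG to its *first* in-frame stop codon (stop
    included); overlapping uORFs from distinct ATGs are all reported.
    Returns (start, end, length) triples in 5'UTR coordinates.
    """
    utr = regions.five_prime_utr.seq
    found = []
    for i in range(len(utr) - 2):
        if utr[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(utr) - 2, 3):
            if utr[j : j + 3] in STOP_CODONS:
                length = j + 3 - i
                if length >= min_coding_nt:
                    found.append((i, j + 3, length))
                break
    return found


@dataclass
class StructuralStats:
    """Per-class length vectors (nt) and their medians."""

    vectors: dict[str, list[int]]
    medians: dict[str, Optional[float]]


def _mono_orf_extent(model: TranscriptModel) -> tuple[int, int]:
    segs = model.orfs[0]
    return segs[0][0], segs[-1][1]


def colinear_mono_pairs(mono_models: list[TranscriptModel],
                        max_nt: int = DEFAULT_COLINEAR_MAX_NT
                        ) -> list[tuple[TranscriptModel, TranscriptModel, int]]:
    """Neighboring same-strand monocistronic gene pairs with ORF
    stop-to-start separation <= max_nt (genomic coordinates).

    Neighbors are consecutive genes in the same-strand ordering of each
    chromosome; genes on the opposite strand do not break adjacency.
    """
    pairs = []
    by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in mono_models:
        by_key.setdefault((m.chrom, m.strand), []).append(m)
    for (chrom, strand), ms in sorted(by_key.items()):
        ms = sorted(ms, key=lambda m: _mono_orf_extent(m)[0])
        for a, b in zip(ms, ms[1:]):
            gap = _mono_orf_extent(b)[0] - _mono_orf_extent(a)[1]
            if 0 <= gap <= max_nt:
                up, down = (a, b) if strand == "+" else (b, a)
                pairs.append((up, down, gap))
    return pairs


def structural_stats(classifications: list[LocusClassification],
                     models: list[TranscriptModel],
                     genome: GenomeSequences,
                     colinear_max_nt: int = DEFAULT_COLINEAR_MAX_NT,
                     min_uorf_nt: int = DEFAULT_MIN_UORF_NT) -> StructuralStats:
    """Length vectors per region class plus colinear and uORF spacings.

    Uses one representative transcript per locus (the first).  Spacings are
    measured stop-to-start, including neither codon.
    """
    by_tid = {m.transcript_id: m for m in models}
    vectors: dict[str, list[int]] = {
        k: [] for k in ("five_prime_utr", "orf1", "orf2", "inter_orf",
                        "mono_orf", "mono_utr", "colinear_spacing", "uorf_spacing")
    }
    mono_models = []
    for c in classifications:
        rep = by_tid[c.transcript_ids[0]]
        if not rep.is_valid:
            warnings.warn(f"skipping invalid model {rep.transcript_id}")
            continue
        rs = extract_regions(rep, genome)
        if c.locus_class == "bicistronic_exclusive":
            vectors["five_prime_utr"].append(rs.five_prime_utr.length)
            vectors["orf1"].append(rs.orf1.length)
            vectors["orf2"].append(rs.orf2.length)
            vectors["inter_orf"].append(rs.inter_orf.length)
        elif c.locus_class == "monocistronic":
            mono_models.append(rep)
            vectors["mono_orf"].append(rs.orf1.length)
            vectors["mono_utr"].append(rs.five_prime_utr.length)
            for _s, e, _l in find_uorfs(rs, min_uorf_nt):
                vectors["uorf_spacing"].append(rs.five_prime_utr.length - e)
    for _up, _down, gap in colinear_mono_pairs(mono_models, colinear_max_nt):
        vectors["colinear_spacing"].append(gap)
    medians = {
        k: (float(np.median(v)) if v else None) for k, v in vectors.items()
    }
    return StructuralStats(vectors=vectors, medians=medians)
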