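"""Colinearity-based conservation calls from tabular homology hits.

Consumes BLAST outfmt-6-like 12-column TSV tables (qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore); the search
itself runs out of process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "HIT_COLUMNS",
    "ColinearCall",
    "GeneInterval",
    "read_hits",
    "load_gene_intervals",
    "reciprocal_best_hits",
    "colinearity_matrix",
]

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MAX_SEPARATION_NT = 20_000

STATUS_TIERS = ("none", "colinear", "colinear+est", "colinear+isoseq")


@dataclass
class GeneInterval:
    gene_id: str
    chrom: str
    strand: str
    start: int   # 0-based half-open
    end: int


@dataclass
class ColinearCall:
    locus_id: str
    species: str
    status: str
    target_pair: Optional[tuple[str, str]] = None


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None, comment="#")


def load_gene_intervals(path) -> dict[str, GeneInterval]:
    """Read ``gene`` features from a GFF3 file into an id-keyed mapping."""
    genes: dict[str, GeneInterval] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].strip().split(";") if "=" in kv
            )
            gid = attrs.get("ID")
            if gid:
                genes[gid] = GeneInterval(gid, cols[0], cols[6],
                                          int(cols[3]) - 1, int(cols[4]))
    return genes


def _best_hits(hits: pd.DataFrame, max_evalue: float) -> dict[str, str]:
    """Best target per query by bitscore; ties broken by lexicographically
    smaller target id (deterministic regardless of row order)."""
    ok = hits[hits["evalue"] <= max_evalue]
    best: dict[str, tuple[float, str]] = {}
    for q, t, b in zip(ok["qseqid"], ok["sseqid"], ok["bitscore"]):
        cur = best.get(q)
        if cur is None or b > cur[0] or (b == cur[0] and t < cur[1]):
            best[q] = (b, t)
    return {q: t for q, (_b, t) in best.items()}


def reciprocal_best_hits(q2t: pd.DataFrame, t2q: pd.DataFrame,
                         max_evalue: float = DEFAULT_MAX_EVALUE) -> dict[str, str]:
    """Ortholog pairs: q's best hit is t, t's best hit is q, both <= max_evalue."""
    fwd = _best_hits(q2t, max_evalue)
    rev = _best_hits(t2q, max_evalue)
    return {q: t for q, t in fwd.items() if rev.get(t) == q}


def _gap_and_between(a: GeneInterval, b: GeneInterval,
                     genes: dict[str, GeneInterval]) -> tuple[int, bool]:
    """Genomic gap between two same-strand genes and whether any other gene
    on that strand intersects the open interval between them."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    gap = max(0, second.start - first.end)
    lo, hi = first.end, second.start
    intervening = any(
        g.gene_id not in (a.gene_id, b.gene_id)
        and g.chrom == a.chrom
        and g.strand == a.strand
        and g.start < hi
        and g.end > lo
        for g in genes.values()
    )
    return gap, intervening


def colinearity_matrix(bicistrons: list[tuple[str, tuple[str, str]]],
                       orthologs: dict[str, str],
                       target_genes: dict[str, GeneInterval],
                       max_separation_nt: int = DEFAULT_MAX_SEPARATION_NT,
                       evidence_flags: dict[str, dict[str, bool]] | None = None,
                       species: str = "target") -> list[ColinearCall]:
    """Call colinear conservation for each (locus_id, (gene1, gene2)) pair.

    Colinear iff both ORFs have orthologs present in the target annotation,
    on the same strand of the same chromosome, with no intervening gene on
    that strand and separation <= ``max_separation_nt``.  ``evidence_flags``
    (locus_id -> {"isoseq": bool, "est": bool}) upgrades the tier.
    """
    evidence_flags = evidence_flags or {}
    calls = []
    for locus_id, (g1, g2) in bicistrons:
        t1, t2 = orthologs.get(g1), orthologs.get(g2)
        status = "none"
        pair = None
        if t1 is not None and t2 is not None:
            gi1, gi2 = target_genes.get(t1), target_genes.get(t2)
            if gi1 is None or gi2 is None:
                missing = t1 if gi1 is None else t2
                warnings.warn(
                    f"{locus_id}: ortholog {missing!r} absent from target annotation"
                )
            elif gi1.chrom == gi2.chrom and gi1.strand == gi2.strand:
                gap, intervening = _gap_and_between(gi1, gi2, target_genes)
                if not intervening and gap <= max_separation_nt:
                    status = "colinear"
                    pair = (t1, t2)
                    ev = evidence_flags.get(locus_id, {})
                    if ev.get("isoseq"):
                        status = "colinear+isoseq"
                    elif ev.get("est"):
                        status = "colinear+est"
        calls.append(ColinearCall(locus_id, species, status, pair))
    return calls
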