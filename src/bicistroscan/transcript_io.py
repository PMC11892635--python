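"""Genome FASTA / GFF3 transcript-model IO and per-locus region extraction.

Coordinate conventions
----------------------
GFF3 on disk is 1-based, end-inclusive.  Everything in memory is 0-based,
half-open ``(start, end)`` — the usual Python slice convention — both for
genomic and transcript coordinates.

GFF3 dialect
------------
Multi-ORF transcripts are encoded with one ``mRNA`` feature whose ``CDS``
children are grouped into ORFs by their ``ID`` attribute: all CDS rows
sharing an ``ID`` form one ORF, and an mRNA's ORFs are its distinct CDS
groups, ordered 5'->3' in transcript orientation.  The CDS ``ID`` doubles as
the per-ORF gene identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequences",
    "TranscriptModel",
    "Region",
    "RegionSet",
    "load_genome",
    "write_genome",
    "load_annotation",
    "write_annotation",
    "extract_regions",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str, record_id: str) -> str:
    """Uppercase, U->T; raise on any character outside ACGTN."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        offset = next(i for i, c in enumerate(s) if c in bad)
        raise ValueError(
            f"non-nucleotide character {s[offset]!r} in record "
            f"{record_id!r} at offset {offset}"
        )
    return s


@dataclass
class GenomeSequences:
    """Mapping of sequence id -> normalized uppercase nucleotide string."""

    records: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> str:
        return self.records[key]

    def __contains__(self, key: str) -> bool:
        return key in self.records

    def __len__(self) -> int:
        return len(self.records)


def load_genome(path) -> GenomeSequences:
    """Read a (multi-)FASTA file into a :class:`GenomeSequences`.

    Lowercase input and RNA bases (U) are normalized; duplicate record ids
    and non-nucleotide characters are hard errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        records[rec.id] = _normalize(str(rec.seq), rec.id)
    return GenomeSequences(records)


def write_genome(genome: GenomeSequences, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class TranscriptModel:
    """One mRNA: exons plus an ordered list of CDS groups (ORFs).

    ``orfs`` holds one list of genomic ``(start, end)`` CDS segments per
    ORF, ordered 5'->3' in transcript orientation; ``gene_ids`` is parallel
    to ``orfs``.
    """

    transcript_id: str
    gene_ids: list[str]
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    orfs: list[list[tuple[int, int]]]
    attributes: dict = field(default_factory=dict)
    is_valid: bool = True

    @property
    def n_orfs(self) -> int:
        return len(self.orfs)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    # -- coordinate mapping ------------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position (must be exonic) to a transcript offset."""
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
        else:
            for s, e in reversed(self.exons):
                if s <= pos < e:
                    return off + (e - 1 - pos)
                off += e - s
        raise ValueError(f"position {pos} not exonic in {self.transcript_id}")

    def orf_transcript_interval(self, orf_index: int) -> tuple[int, int]:
        """Transcript-coordinate interval of an ORF (must be contiguous)."""
        positions = []
        for s, e in self.orfs[orf_index]:
            positions.append(self.genomic_to_transcript(s if self.strand == "+" else e - 1))
            positions.append(self.genomic_to_transcript(e - 1 if self.strand == "+" else s))
        lo, hi = min(positions), max(positions) + 1
        length = sum(e - s for s, e in self.orfs[orf_index])
        if hi - lo != length:
            raise ValueError(
                f"ORF {orf_index} of {self.transcript_id} is not contiguous "
                "in transcript coordinates"
            )
        return lo, hi


@dataclass
class Region:
    """A transcript-coordinate interval and its 5'->3' mRNA sequence."""

    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Extracted regions of one transcript; all sequences read 5'->3'.

    ``inter_orf`` / ``orf2`` are None for monocistronic models.  The present
    regions concatenate, in order, to the full spliced transcript sequence.
    """

    transcript_id: str
    five_prime_utr: Region
    orf1: Region
    inter_orf: Optional[Region]
    orf2: Optional[Region]
    three_prime_utr: Region
    gene_ids: list[str] = field(default_factory=list)

    @property
    def is_bicistronic(self) -> bool:
        return self.orf2 is not None

    @property
    def mrna(self) -> str:
        parts = [self.five_prime_utr.seq, self.orf1.seq]
        if self.inter_orf is not None:
            parts.append(self.inter_orf.seq)
        if self.orf2 is not None:
            parts.append(self.orf2.seq)
        parts.append(self.three_prime_utr.seq)
        return "".join(parts)

    def regions(self) -> dict[str, Region]:
        out = {"five_prime_utr": self.five_prime_utr, "orf1": self.orf1}
        if self.inter_orf is not None:
            out["inter_orf"] = self.inter_orf
        if self.orf2 is not None:
            out["orf2"] = self.orf2
        out["three_prime_utr"] = self.three_prime_utr
        return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def load_annotation(path, genome: GenomeSequences) -> list[TranscriptModel]:
    """Parse GFF3 into :class:`TranscriptModel` objects.

    CDS rows grouped by ``ID`` form ORFs (see module docstring).  Models
    whose CDS-group length is not divisible by 3 are flagged invalid with a
    warning; a CDS outside its mRNA's exons or an unknown chromosome is a
    hard error.
    """
    mrnas: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, dict[str, list[tuple[int, int]]]] = {}

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr_text = cols
            attrs = _parse_attributes(attr_text)
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            if ftype == "mRNA":
                tid = attrs.get("ID")
                if tid is None:
                    raise ValueError("mRNA feature without ID attribute")
                mrnas[tid] = {"chrom": chrom, "strand": strand, "attrs": attrs}
            elif ftype == "exon":
                exons.setdefault(attrs.get("Parent", ""), []).append(iv)
            elif ftype == "CDS":
                parent = attrs.get("Parent", "")
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"CDS without ID attribute (parent {parent!r})")
                cds.setdefault(parent, {}).setdefault(gid, []).append(iv)

    models = []
    for tid, meta in mrnas.items():
        chrom = meta["chrom"]
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} of {tid!r} absent from genome")
        ex = sorted(exons.get(tid, []))
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {tid!r}")
        groups = cds.get(tid, {})
        orf_list = []
        for gid, segs in groups.items():
            segs = sorted(segs)
            for cs, ce in segs:
                if not any(es <= cs and ce <= ee for es, ee in ex):
                    raise ValueError(
                        f"CDS {gid!r} segment ({cs + 1}-{ce}) outside exons of {tid!r}"
                    )
            orf_list.append((gid, segs))
        model = TranscriptModel(
            transcript_id=tid,
            gene_ids=[g for g, _ in orf_list],
            chrom=chrom,
            strand=meta["strand"],
            exons=ex,
            orfs=[segs for _, segs in orf_list],
            attributes=meta["attrs"],
        )
        _order_and_validate_orfs(model)
        models.append(model)
    return models


def _order_and_validate_orfs(model: TranscriptModel) -> None:
    """Sort ORFs 5'->3' in transcript orientation and apply invariants."""
    try:
        ivs = [model.orf_transcript_interval(i) for i in range(model.n_orfs)]
    except ValueError:
        model.is_valid = False
        warnings.warn(f"{model.transcript_id}: discontiguous ORF; model flagged invalid")
        return
    order = sorted(range(model.n_orfs), key=lambda i: ivs[i][0])
    model.orfs = [model.orfs[i] for i in order]
    model.gene_ids = [model.gene_ids[i] for i in order]
    ivs = [ivs[i] for i in order]
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 < a1:
            raise ValueError(f"{model.transcript_id}: ORFs overlap in transcript coordinates")
    for i, (lo, hi) in enumerate(ivs):
        if (hi - lo) % 3 != 0:
            warnings.warn(
                f"{model.transcript_id}: ORF {model.gene_ids[i]} length "
                f"{hi - lo} not divisible by 3; model flagged invalid"
            )
            model.is_valid = False


def write_annotation(models: Iterable[TranscriptModel], path) -> None:
    """Write models back to the GFF3 dialect read by :func:`load_annotation`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span_s, span_e = m.span
            fh.write(
                "\t".join(
                    [m.chrom, "bicistroscan", "mRNA", str(span_s + 1), str(span_e),
                     ".", m.strand, ".", f"ID={m.transcript_id}"]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [m.chrom, "bicistroscan", "exon", str(s + 1), str(e),
                         ".", m.strand, ".", f"Parent={m.transcript_id}"]
                    )
                    + "\n"
                )
            for gid, segs in zip(m.gene_ids, m.orfs):
                ordered = segs if m.strand == "+" else list(reversed(segs))
                cum = 0
                for s, e in ordered:
                    phase = (3 - cum % 3) % 3
                    fh.write(
                        "\t".join(
                            [m.chrom, "bicistroscan", "CDS", str(s + 1), str(e),
                             ".", m.strand, str(phase),
                             f"ID={gid};Parent={m.transcript_id}"]
                        )
                        + "\n"
                    )
                    cum += e - s


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------


def spliced_sequence(model: TranscriptModel, genome: GenomeSequences) -> str:
    """Spliced transcript sequence, 5'->3' of the mRNA."""
    chrom_seq = genome[model.chrom]
    s = "".join(chrom_seq[a:b] for a, b in model.exons)
    return s if model.strand == "+" else revcomp(s)


def extract_regions(model: TranscriptModel, genome: GenomeSequences) -> RegionSet:
    """Cut a transcript into 5'UTR / ORF1 / inter-ORF / ORF2 / 3'UTR.

    Minus-strand models are reverse-complemented first, so all region
    sequences read 5'->3' of the mRNA and the concatenation of the present
    regions equals the spliced transcript sequence.
    """
    if model.n_orfs == 0:
        raise ValueError(f"{model.transcript_id}: no ORFs")
    if model.n_orfs > 2:
        raise ValueError(
            f"{model.transcript_id}: extract_regions supports at most 2 ORFs "
            f"(got {model.n_orfs})"
        )
    mrna = spliced_sequence(model, genome)
    ivs = [model.orf_transcript_interval(i) for i in range(model.n_orfs)]

    def region(a: int, b: int) -> Region:
        return Region(a, b, mrna[a:b])

    (s1, e1) = ivs[0]
    if model.n_orfs == 1:
        return RegionSet(
            transcript_id=model.transcript_id,
            five_prime_utr=region(0, s1),
            orf1=region(s1, e1),
            inter_orf=None,
            orf2=None,
            three_prime_utr=region(e1, len(mrna)),
            gene_ids=list(model.gene_ids),
        )
    (s2, e2) = ivs[1]
    return RegionSet(
        transcript_id=model.transcript_id,
        five_prime_utr=region(0, s1),
        orf1=region(s1, e1),
        inter_orf=region(e1, s2),
        orf2=region(s2, e2),
        three_prime_utr=region(e2, len(mrna)),
        gene_ids=list(model.gene_ids),
    )
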