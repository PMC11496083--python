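"""Exon-level model of a single gene locus.

The quantification method never needs full transcript structures: it works on
the *union exon set* of one gene (for CD45, the ``PTPRC`` locus), i.e. every
distinct exon interval that appears in any annotated transcript, ordered
5'->3' in transcript orientation and carrying its genomic sequence.

Coordinate conventions
----------------------
External interfaces (GTF, region strings) are 1-based inclusive, matching
samtools/Ensembl conventions.  The :class:`Exon` dataclass stores the GTF
coordinates verbatim; helper properties expose 0-based half-open forms where
internal code needs them.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, replace
from typing import Sequence

import gffutils
from Bio.Seq import reverse_complement
from pyfaidx import Fasta

__all__ = [
    "Exon",
    "GeneModel",
    "parse_gtf_exons",
    "attach_sequences",
    "locus_region",
    "model_to_gtf",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Exon:
    """One exon of the union exon set.

    ``start``/``end`` are 1-based inclusive genomic coordinates.  ``sequence``
    is uppercase DNA in transcript (5'->3') orientation, i.e. already
    reverse-complemented for minus-strand genes; it is ``None`` until
    :func:`attach_sequences` has run.
    """

    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon {self.exon_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"exon {self.exon_id}: bad strand {self.strand!r}")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"exon {self.exon_id}: sequence length {len(self.sequence)} "
                    f"!= span {self.length}"
                )
            if not set(self.sequence) <= _ALPHABET:
                raise ValueError(f"exon {self.exon_id}: non-ACGTN characters")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (== 1-based inclusive end)."""
        return self.end


@dataclass(frozen=True)
class GeneModel:
    """Union exon set of one gene, ordered 5'->3' in transcript orientation."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene model must contain at least one exon")
        starts = [e.start for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if len(set(starts)) != len(starts) or not ordered:
            raise ValueError("exons must be strictly ordered 5'->3' in transcript orientation")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end >= b.start:
                raise ValueError(f"exons {a.exon_id} and {b.exon_id} overlap")

    @property
    def locus_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def locus_end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def exon_ids(self) -> tuple[str, ...]:
        return tuple(e.exon_id for e in self.exons)

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(exon_id)

    def exon_index(self, exon_id: str) -> int:
        """Position of an exon in transcript order (0-based)."""
        for i, e in enumerate(self.exons):
            if e.exon_id == exon_id:
                return i
        raise KeyError(exon_id)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [
                {
                    "exon_id": e.exon_id,
                    "start": e.start,
                    "end": e.end,
                    "sequence": e.sequence,
                }
                for e in self.exons
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _read_text(path) -> str:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return fh.read()


def parse_gtf_exons(gtf_path, gene_id: str) -> GeneModel:
    """Parse the union exon set of ``gene_id`` from an Ensembl-dialect GTF.

    Exons are merged across transcripts by exact (start, end); overlapping but
    unequal intervals are kept as distinct exons.  Default labels are
    ``E1..En`` in transcript (5'->3') order.
    """
    db = gffutils.create_db(
        _read_text(gtf_path),
        ":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    gene_seen = False
    coords: dict[tuple[int, int], None] = {}
    chroms: set[str] = set()
    strands: set[str] = set()
    for feat in db.all_features():
        if feat.attributes.get("gene_id", [None])[0] != gene_id:
            continue
        gene_seen = True
        if feat.featuretype != "exon":
            continue
        coords[(feat.start, feat.end)] = None
        chroms.add(feat.seqid)
        strands.add(feat.strand)
    if not gene_seen:
        raise ValueError(f"gene not found: {gene_id!r}")
    if not coords:
        raise ValueError(f"no exons for gene {gene_id!r}")
    if len(strands) != 1 or strands <= {".", "?"}:
        raise ValueError(f"inconsistent strand for gene {gene_id!r}: {sorted(strands)}")
    if len(chroms) != 1:
        raise ValueError(f"gene {gene_id!r} spans multiple chromosomes: {sorted(chroms)}")
    strand = strands.pop()
    chrom = chroms.pop()
    ordered = sorted(coords, key=lambda c: c[0], reverse=(strand == "-"))
    exons = tuple(
        Exon(exon_id=f"E{i + 1}", chrom=chrom, start=s, end=e, strand=strand)
        for i, (s, e) in enumerate(ordered)
    )
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)


def attach_sequences(model: GeneModel, genome_fasta) -> GeneModel:
    """Return a copy of ``model`` with transcript-orientation sequences attached.

    Minus-strand exons are reverse-complemented so every sequence reads 5'->3'
    along the transcript.  Ambiguity codes other than N are not expected in
    genome builds and are rejected by the :class:`Exon` invariant.
    """
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    if model.chrom not in fasta:
        raise ValueError(f"chromosome {model.chrom!r} not in FASTA")
    chrom_len = len(fasta[model.chrom])
    exons = []
    for e in model.exons:
        if e.end > chrom_len:
            raise ValueError(
                f"exon {e.exon_id} span {e.start}-{e.end} exceeds chromosome "
                f"length {chrom_len}"
            )
        seq = str(fasta[model.chrom][e.start0 : e.end0])
        if model.strand == "-":
            seq = reverse_complement(seq)
        exons.append(replace(e, sequence=seq))
    return replace(model, exons=tuple(exons))


def locus_region(model: GeneModel, pad: int = 0) -> str:
    """1-based inclusive region string covering every exon, padded by ``pad``.

    The start clamps at 1; chromosome-end clamping is left to the reader of the
    region (alignment fetchers tolerate overhang on the right).
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    start = max(1, model.locus_start - pad)
    end = model.locus_end + pad
    return f"{model.chrom}:{start}-{end}"


def model_to_gtf(model: GeneModel, transcript_id: str | None = None) -> str:
    """Serialize the union exon set as Ensembl-dialect GTF text.

    Re-parsing the output with :func:`parse_gtf_exons` reproduces the model
    (default labels, no sequences).
    """
    tid = transcript_id or f"{model.gene_id}-t1"
    lines = []
    for e in sorted(model.exons, key=lambda e: e.start):
        attrs = f'gene_id "{model.gene_id}"; transcript_id "{tid}"; exon_id "{e.exon_id}";'
        lines.append(
            "\t".join(
                [
                    model.chrom,
                    "cd45iso",
                    "exon",
                    str(e.start),
                    str(e.end),
                    ".",
                    model.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"
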