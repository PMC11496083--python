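"""Extraction of barcoded, UMI-tagged reads from 10x-style alignments.

Accepts BAM or SAM produced by Cell Ranger-like pipelines: cell barcodes in
``CB`` (corrected) or ``CR`` (raw) tags, UMIs in ``UB``/``UR``, optional
``NH`` hit counts.  Only primary, mapped, non-supplementary alignments are
used; records missing both barcode tags or both UMI tags are dropped (counted
in the module logger).  Coordinates are 0-based half-open internally; region
strings follow the 1-based inclusive samtools convention.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "parse_region",
    "extract_locus_reads",
    "infer_read_length",
    "split_by_length",
    "subsample",
    "reads_per_cell",
    "read_whitelist",
    "write_fastq",
]


@dataclass(frozen=True)
class ReadRecord:
    """One retained alignment record.

    ``sequence`` is the aligned-orientation sequence as stored in SAM (reverse
    strand alignments store the reverse complement of the sequenced read);
    classification checks both strands, so orientation never matters
    downstream.  ``pos`` is the 0-based leftmost aligned position and
    ``cigar`` a tuple of pysam-style (op, length) pairs.
    """

    qname: str
    barcode: str
    umi: str
    sequence: str
    chrom: str
    pos: int
    cigar: tuple[tuple[int, int], ...]
    mapq: int
    is_reverse: bool = False
    nh: int | None = None

    def __post_init__(self) -> None:
        if not self.barcode or not self.umi:
            raise ValueError("retained records must carry a barcode and a UMI")


def parse_region(region: str) -> tuple[str, int, int]:
    """Split ``chrom:start-end`` (1-based inclusive) into (chrom, start0, end0)."""
    chrom, _, span = region.rpartition(":")
    try:
        start_s, end_s = span.split("-")
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    except ValueError:
        raise ValueError(f"malformed region string {region!r}") from None
    if not chrom or start < 1 or end < start:
        raise ValueError(f"malformed region string {region!r}")
    return chrom, start - 1, end


def _tag(aln: pysam.AlignedSegment, *names: str) -> str | None:
    for name in names:
        if aln.has_tag(name):
            value = aln.get_tag(name)
            if value:
                return str(value)
    return None


def extract_locus_reads(
    path,
    region: str,
    barcode_whitelist: Iterable[str] | None = None,
) -> Iterator[ReadRecord]:
    """Yield barcoded reads whose alignment overlaps ``region``.

    Uses the index for random access when available, otherwise falls back to a
    linear scan (SAM text, unindexed BAM).  Secondary/supplementary and
    unmapped records are skipped; ``CB`` is preferred over ``CR`` and ``UB``
    over ``UR``.
    """
    chrom, start0, end0 = parse_region(region)
    whitelist = set(barcode_whitelist) if barcode_whitelist is not None else None
    dropped_untagged = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        try:
            iterator = af.fetch(chrom, start0, end0)
        except ValueError:
            iterator = (
                aln
                for aln in af.fetch(until_eof=True)
                if not aln.is_unmapped
                and aln.reference_name == chrom
                and aln.reference_start < end0
                and (aln.reference_end or aln.reference_start + 1) > start0
            )
        for aln in iterator:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            barcode = _tag(aln, "CB", "CR")
            umi = _tag(aln, "UB", "UR")
            if barcode is None or umi is None:
                dropped_untagged += 1
                continue
            if whitelist is not None and barcode not in whitelist:
                continue
            if aln.query_sequence is None or aln.cigartuples is None:
                continue
            yield ReadRecord(
                qname=aln.query_name,
                barcode=barcode,
                umi=umi,
                sequence=aln.query_sequence.upper(),
                chrom=aln.reference_name,
                pos=aln.reference_start,
                cigar=tuple(aln.cigartuples),
                mapq=aln.mapping_quality,
                is_reverse=aln.is_reverse,
                nh=aln.get_tag("NH") if aln.has_tag("NH") else None,
            )
    if dropped_untagged:
        logger.info("dropped %d reads lacking barcode or UMI tags", dropped_untagged)


def infer_read_length(records: Iterable[ReadRecord]) -> int:
    """Modal sequence length; ties break toward the larger length."""
    counts: dict[int, int] = {}
    for rec in records:
        counts[len(rec.sequence)] = counts.get(len(rec.sequence), 0) + 1
    if not counts:
        raise ValueError("cannot infer read length from zero records")
    return max(counts, key=lambda length: (counts[length], length))


def split_by_length(
    records: Iterable[ReadRecord], threshold: int = 100
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Partition records into (length <= threshold, length > threshold)."""
    short: list[ReadRecord] = []
    long: list[ReadRecord] = []
    for rec in records:
        (short if len(rec.sequence) <= threshold else long).append(rec)
    return short, long


def _keep_fraction(seed: int, qname: str) -> float:
    digest = hashlib.sha256(f"{seed}:{qname}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def subsample(
    records: Sequence[ReadRecord], fraction: float, seed: int = 42
) -> list[ReadRecord]:
    """Deterministic qname-hash subsampling (the samtools contract).

    Every record of a qname shares fate, so mates and duplicate alignments
    stay together, and subsets are nested across fractions for a fixed seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction == 1.0:
        return list(records)
    return [r for r in records if _keep_fraction(seed, r.qname) < fraction]


def _unique_mapper(mapq: int, nh: int | None) -> bool:
    # NH==1 when reported; Cell Ranger/STAR mark unique mappers with MAPQ 255
    return nh == 1 if nh is not None else mapq == 255


def reads_per_cell(source, whitelist: Sequence[str]) -> float:
    """Mean uniquely-mapped read count per whitelisted cell.

    Counts primary, mapped, non-supplementary records mapping to the genome
    exactly once (NH==1, falling back to MAPQ 255 when NH is absent) whose
    barcode is whitelisted, divided by the whitelist size — cells with zero
    reads still count in the denominator.  ``source`` may be a BAM/SAM path or
    an iterable of :class:`ReadRecord`.
    """
    cells = list(whitelist)
    if not cells:
        raise ValueError("whitelist must be non-empty")
    cellset = set(cells)
    n = 0
    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source), check_sq=False) as af:
            for aln in af.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                barcode = _tag(aln, "CB", "CR")
                if barcode not in cellset:
                    continue
                nh = aln.get_tag("NH") if aln.has_tag("NH") else None
                if _unique_mapper(aln.mapping_quality, nh):
                    n += 1
    else:
        for rec in source:
            if rec.barcode in cellset and _unique_mapper(rec.mapq, rec.nh):
                n += 1
    return n / len(cells)


def read_whitelist(path) -> list[str]:
    """Read a one-barcode-per-line whitelist, preserving order."""
    barcodes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("whitelist contains duplicate barcodes")
    return barcodes


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Export records as FASTQ, carrying barcode and UMI in the read id."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.qname}|CB:{rec.barcode}|UB:{rec.umi}\n")
            fh.write(f"{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")
            n += 1
    return n
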