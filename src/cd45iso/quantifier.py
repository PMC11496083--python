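"""Read classification and per-cell isoform counting.

Two independent classifiers are provided:

* :func:`classify_read` — k-mer pseudo-alignment against the flanked
  reference.  For each reference sequence the fraction of the read's k-mers
  found in it (best strand) is computed; references at or above
  ``min_kmer_frac`` are hits, collapsed to feature level.  This is the
  production path.
* :func:`classify_read_genomic` — a CIGAR-walking oracle that measures the
  genomic overlap of the aligned blocks with feature exons (and N-gap
  adjacency for junctions).  It shares no code or data structures with the
  k-mer path and is used to validate it.

Counting collapses reads by (cell barcode, UMI): each molecule contributes a
total weight of 1, split equally across the union of its reads' feature sets
(a molecule matching n features adds 1/n to each — the weight-splitting rule
for multi-mapping reads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from Bio.Seq import reverse_complement

from .bam_reads import ReadRecord, infer_read_length, split_by_length
from .gene_model import GeneModel
from .reference_builder import BuildRules, ReferenceSet, build_reference

__all__ = [
    "FeatureIndex",
    "Assignment",
    "CountMatrix",
    "build_index",
    "classify_read",
    "classify_read_genomic",
    "quantify",
    "merge_counts",
    "log_normalize",
    "quantify_records",
    "quantify_split",
]

# pysam CIGAR operation codes
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_EQ, _CIG_X = 0, 1, 2, 3, 4, 7, 8
_QUERY_OPS = {_CIG_M, _CIG_I, _CIG_S, _CIG_EQ, _CIG_X}
_ALIGN_OPS = {_CIG_M, _CIG_EQ, _CIG_X}


@dataclass(frozen=True)
class FeatureIndex:
    """Positional k-mer lookup over a reference set (reference strand only).

    Each k-mer maps to the (ref_id, position) pairs where it occurs, so
    classification can demand co-linear (single-diagonal) hits rather than a
    bag-of-k-mers match — a junction-spanning read must not count k-mers from
    the two flank contexts of a reference in which they are not adjacent.
    """

    k: int
    kmer_map: Mapping[str, tuple[tuple[str, int], ...]]
    refset: ReferenceSet

    @property
    def feature_map(self) -> dict[str, str]:
        return self.refset.feature_map


@dataclass(frozen=True)
class Assignment:
    """Feature-level classification of one read."""

    qname: str
    barcode: str
    umi: str
    features: frozenset[str]


class CountMatrix:
    """Sparse features x barcodes matrix of (possibly fractional) counts."""

    def __init__(
        self,
        feature_names: Sequence[str],
        barcodes: Sequence[str],
        values,
    ) -> None:
        self.feature_names = list(feature_names)
        self.barcodes = list(barcodes)
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes in count matrix")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names in count matrix")
        X = sp.csr_matrix(values, dtype=np.float64)
        if X.shape != (len(self.feature_names), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {X.shape} inconsistent with "
                f"{len(self.feature_names)} features x {len(self.barcodes)} barcodes"
            )
        if X.nnz and X.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        self.values = X

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature_vector(self, feature: str) -> np.ndarray:
        """Dense count vector over barcodes for one feature."""
        try:
            i = self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None
        return np.asarray(self.values[i].todense()).ravel()

    def total(self) -> float:
        return float(self.values.sum())

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CountMatrix({len(self.feature_names)} features x "
            f"{len(self.barcodes)} barcodes, nnz={self.values.nnz})"
        )


def build_index(refset: ReferenceSet, k: int = 21) -> FeatureIndex:
    """Index every k-mer of every reference sequence.

    Reads are checked on both strands at query time, so only the reference
    strand is stored.  k below 11 offers too little specificity against a
    mammalian-scale locus and is rejected.
    """
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    shortest = min(len(t.sequence) for t in refset.transcripts)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest reference length {shortest}")
    kmer_map: dict[str, list[tuple[str, int]]] = {}
    for t in refset.transcripts:
        seq = t.sequence
        for i in range(len(seq) - k + 1):
            kmer_map.setdefault(seq[i : i + k], []).append((t.ref_id, i))
    return FeatureIndex(
        k=k,
        kmer_map={kmer: tuple(hits) for kmer, hits in kmer_map.items()},
        refset=refset,
    )


def classify_read(
    sequence: str, index: FeatureIndex, min_kmer_frac: float = 0.7
) -> frozenset[str]:
    """Feature set supported by a read, by co-linear k-mer fraction.

    For each reference, k-mer hits are binned by alignment diagonal
    (reference position minus read position) and the best-supported diagonal
    on the best strand is scored; substitution errors only remove the k-mers
    they touch, while hits from non-adjacent parts of a reference cannot
    combine.  References at or above ``min_kmer_frac`` are collapsed to
    feature level; the empty set marks an unassignable read.
    """
    k = index.k
    sequence = sequence.upper()
    n_kmers = len(sequence) - k + 1
    if n_kmers <= 0:
        return frozenset()
    best: Counter[str] = Counter()
    for strand_seq in (sequence, reverse_complement(sequence)):
        diagonals: Counter[tuple[str, int]] = Counter()
        for i in range(n_kmers):
            for ref_id, pos in index.kmer_map.get(strand_seq[i : i + k], ()):
                diagonals[(ref_id, pos - i)] += 1
        for (ref_id, _diag), count in diagonals.items():
            if count > best[ref_id]:
                best[ref_id] = count
    feature_map = index.feature_map
    return frozenset(
        feature_map[ref_id]
        for ref_id, count in best.items()
        if count / n_kmers >= min_kmer_frac
    )


def _aligned_segments(
    record: ReadRecord,
) -> tuple[list[list[tuple[int, int]]], list[tuple[int, int]]]:
    """Genomic M-intervals grouped into segments split at N gaps.

    Returns (segments, gaps) where each gap is the (end, start) genomic
    half-open boundary pair of one N operation.
    """
    segments: list[list[tuple[int, int]]] = [[]]
    gaps: list[tuple[int, int]] = []
    pos = record.pos
    for op, length in record.cigar:
        if op in _ALIGN_OPS:
            segments[-1].append((pos, pos + length))
            pos += length
        elif op == _CIG_D:
            pos += length
        elif op == _CIG_N:
            gaps.append((pos, pos + length))
            pos += length
            segments.append([])
        # insertions/clips consume no reference
    return segments, gaps


def classify_read_genomic(
    record: ReadRecord,
    model: GeneModel,
    rules: BuildRules,
    k: int = 1,
) -> frozenset[str]:
    """Oracle classifier working on genomic alignment geometry only.

    An exon feature is reported when the aligned (M/=/X) blocks overlap the
    exon by at least ``k`` bases in total.  A junction feature (L, R) is
    reported when some N gap joins a block ending exactly at L's
    transcript-3' genomic boundary to a block starting exactly at R's
    transcript-5' boundary, with at least ``k`` aligned bases on each side of
    the gap.
    """
    if record.chrom != model.chrom:
        return frozenset()
    segments, gaps = _aligned_segments(record)
    features: set[str] = set()
    for feat in rules.features:
        if feat.kind == "exon":
            exon = model.exon(feat.target)  # type: ignore[arg-type]
            overlap = 0
            for seg in segments:
                for s, e in seg:
                    overlap += max(0, min(e, exon.end0) - max(s, exon.start0))
            if overlap >= k:
                features.add(feat.name)
        else:
            left, right = (model.exon(x) for x in feat.target)  # type: ignore[misc]
            genomic_left, genomic_right = sorted((left, right), key=lambda e: e.start)
            for i, (gap_start, gap_end) in enumerate(gaps):
                if gap_start != genomic_left.end0 or gap_end != genomic_right.start0:
                    continue
                before = sum(e - s for seg in segments[: i + 1] for s, e in seg)
                after = sum(e - s for seg in segments[i + 1 :] for s, e in seg)
                if before >= k and after >= k:
                    features.add(feat.name)
    return frozenset(features)


def classify_records(
    records: Iterable[ReadRecord],
    index: FeatureIndex,
    min_kmer_frac: float = 0.7,
) -> list[Assignment]:
    """Classify a batch of records with the k-mer classifier."""
    return [
        Assignment(
            qname=r.qname,
            barcode=r.barcode,
            umi=r.umi,
            features=classify_read(r.sequence, index, min_kmer_frac),
        )
        for r in records
    ]


def quantify(
    assignments: Iterable[Assignment],
    feature_names: Sequence[str],
    whitelist: Sequence[str] | None = None,
    forced_cells: int | None = None,
) -> CountMatrix:
    """UMI-deduplicated per-cell counts with multi-feature weight splitting.

    Reads are grouped by (barcode, UMI); a group's feature set is the union of
    its reads' sets and contributes weight 1 split equally across it.  Columns
    are the whitelist (every listed barcode appears, even all-zero) or, in
    forced-cells mode, the top ``forced_cells`` barcodes by total weight
    (ties broken lexicographically).
    """
    if whitelist is not None and forced_cells is not None:
        raise ValueError("use either a whitelist or forced-cells mode, not both")
    groups: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        groups.setdefault((a.barcode, a.umi), set()).update(a.features)
    weights: dict[str, Counter[str]] = {}
    for (barcode, _umi), feats in groups.items():
        if not feats:
            continue
        w = 1.0 / len(feats)
        cell = weights.setdefault(barcode, Counter())
        for f in feats:
            cell[f] += w
    if whitelist is not None:
        barcodes = list(whitelist)
        if not barcodes:
            raise ValueError("whitelist must be non-empty")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("whitelist contains duplicate barcodes")
    else:
        n = forced_cells if forced_cells is not None else 3000
        totals = {bc: sum(c.values()) for bc, c in weights.items()}
        barcodes = sorted(totals, key=lambda bc: (-totals[bc], bc))[:n]
    feat_idx = {f: i for i, f in enumerate(feature_names)}
    col_idx = {bc: j for j, bc in enumerate(barcodes)}
    rows, cols, data = [], [], []
    for bc, cell in weights.items():
        j = col_idx.get(bc)
        if j is None:
            continue
        for f, w in cell.items():
            if f not in feat_idx:
                raise ValueError(f"assignment references undeclared feature {f!r}")
            rows.append(feat_idx[f])
            cols.append(j)
            data.append(w)
    X = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(feature_names), len(barcodes))
    )
    return CountMatrix(feature_names, barcodes, X)


def merge_counts(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Element-wise sum over the union of barcodes (same feature set)."""
    if a.feature_names != b.feature_names:
        raise ValueError("cannot merge count matrices with different features")
    barcodes = list(a.barcodes) + [bc for bc in b.barcodes if bc not in set(a.barcodes)]
    idx = {bc: j for j, bc in enumerate(barcodes)}
    shape = (len(a.feature_names), len(barcodes))
    out = sp.lil_matrix(shape)
    for m in (a, b):
        coo = m.values.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            out[i, idx[m.barcodes[j]]] += v
    return CountMatrix(a.feature_names, barcodes, out)


def log_normalize(m: CountMatrix, scale: float = 10_000.0) -> np.ndarray:
    """Per-cell log2(1 + scale * count / total) normalization (dense).

    Totals are taken within this matrix (isoform features only), matching how
    single-cell assays are normalized per modality; all-zero cells stay zero.
    """
    dense = m.to_dense()
    totals = dense.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(totals > 0, dense * (scale / np.where(totals > 0, totals, 1.0)), 0.0)
    return np.log2(1.0 + scaled)


def quantify_records(
    records: Sequence[ReadRecord],
    model: GeneModel,
    rules: BuildRules,
    read_len: int | None = None,
    min_overlap: int = 1,
    k: int = 21,
    min_kmer_frac: float = 0.7,
    whitelist: Sequence[str] | None = None,
    forced_cells: int | None = None,
) -> CountMatrix:
    """Reference building + classification + counting for one read group.

    ``read_len`` defaults to the modal length of the records, mirroring the
    automatic R2-length detection of the original workflow.
    """
    feature_names = list(rules.feature_names)
    if not records:
        return CountMatrix(
            feature_names,
            list(whitelist) if whitelist else [],
            sp.csr_matrix((len(feature_names), len(whitelist) if whitelist else 0)),
        )
    if read_len is None:
        read_len = infer_read_length(records)
    refset = build_reference(model, rules, read_len, min_overlap)
    index = build_index(refset, k)
    assignments = classify_records(records, index, min_kmer_frac)
    return quantify(assignments, feature_names, whitelist=whitelist, forced_cells=forced_cells)


def quantify_split(
    records: Sequence[ReadRecord],
    model: GeneModel,
    rules: BuildRules,
    length_threshold: int = 100,
    **kwargs,
) -> CountMatrix:
    """Quantify short (<= threshold) and long read groups separately and sum.

    Mixed-length runs (e.g. resequenced libraries) are handled by building a
    reference per group at that group's own read length, then adding the two
    count matrices.
    """
    short, long = split_by_length(records, length_threshold)
    if not short or not long:
        return quantify_records(records, model, rules, **kwargs)
    kwargs.pop("read_len", None)
    a = quantify_records(short, model, rules, **kwargs)
    b = quantify_records(long, model, rules, **kwargs)
    return merge_counts(a, b)
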