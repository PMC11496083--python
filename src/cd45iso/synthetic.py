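"""Synthetic toy locus, isoform transcripts and barcoded spliced reads.

The generator emulates the structure the quantifier targets: a multi-exon
gene whose exons at transcript positions 4, 5 and 6 are alternatively spliced
(features RA, RB, RC), with the skip-all isoform joining exon 3 directly to
exon 7 (feature RO).  Reads are sampled from spliced transcripts and lifted
back to genomic coordinates with correct N-gap CIGARs, tagged with cell
barcodes and UMIs, so the whole pipeline can run end to end with a known
truth table and no external data.

Barcodes are 16-mers and UMIs 12-mers (10x tag shapes), both generated by
deterministic base-4 index encoding so molecules never collide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .gene_model import Exon, GeneModel, model_to_gtf

__all__ = [
    "TruthTable",
    "make_toy_model",
    "make_barcodes",
    "make_cell_profiles",
    "isoform_sequence",
    "isoform_labels",
    "label_features",
    "simulate_reads",
    "write_fixture",
]

_BASES = np.array(list("ACGT"))

#: All isoform labels expressible over the three alternative exons.
ALL_LABELS = ("RABC", "RAB", "RAC", "RBC", "RA", "RB", "RC", "RO")

# transcript positions (0-based) of the alternative exons A, B, C
_ALT_POSITIONS = {"A": 3, "B": 4, "C": 5}


def isoform_labels() -> tuple[str, ...]:
    return ALL_LABELS


def label_features(label: str) -> frozenset[str]:
    """Feature set implied by an isoform label (RA in set iff A included...)."""
    _check_label(label)
    if label == "RO":
        return frozenset({"RO"})
    return frozenset(f"R{c}" for c in label[1:])


def _check_label(label: str) -> None:
    if label == "RO":
        return
    letters = label[1:]
    if (
        not label.startswith("R")
        or not letters
        or any(c not in "ABC" for c in letters)
        or list(letters) != sorted(set(letters))
    ):
        raise ValueError(f"invalid isoform label {label!r}")


def _encode_index(index: int, length: int) -> str:
    digits = []
    for _ in range(length):
        digits.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(digits))


def make_barcodes(n: int, length: int = 16) -> list[str]:
    """``n`` distinct 10x-shaped cell barcodes (deterministic)."""
    return [_encode_index(i, length) for i in range(n)]


def make_toy_model(
    n_exons: int = 9,
    exon_len_range: tuple[int, int] = (120, 200),
    intron_len_range: tuple[int, int] = (200, 400),
    seed: int = 0,
    chrom: str = "chrS",
    gene_id: str = "PTPRC_TOY",
    strand: str = "+",
    flank_pad: int = 200,
) -> tuple[GeneModel, str]:
    """Random toy gene embedded in a random genome.

    Returns the sequence-attached model and the genome FASTA text.  Identical
    arguments yield identical output.
    """
    if n_exons < 7:
        raise ValueError("need at least 7 exons for the CD45-like topology")
    lo, hi = exon_len_range
    ilo, ihi = intron_len_range
    if not (1 <= lo <= hi) or not (1 <= ilo <= ihi):
        raise ValueError("invalid length ranges")
    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(lo, hi + 1, size=n_exons)
    intron_lens = rng.integers(ilo, ihi + 1, size=n_exons - 1)
    genome_len = flank_pad * 2 + int(exon_lens.sum() + intron_lens.sum())
    genome_arr = rng.choice(_BASES, size=genome_len)

    spans = []
    pos = flank_pad  # 0-based
    for i, elen in enumerate(exon_lens):
        spans.append((pos, pos + int(elen)))
        pos += int(elen)
        if i < n_exons - 1:
            pos += int(intron_lens[i])

    ordered = spans if strand == "+" else list(reversed(spans))

    # Make alternative splice contexts locally distinguishable: exons that can
    # appear as alternative successors (transcript positions 4..7) get
    # pairwise-distinct first bases, alternative predecessors (3..6) distinct
    # last bases.  Boundary contexts identical in sequence are inherently
    # unresolvable by any sequence-based classifier (such reads simply
    # multi-map); real splice acceptor/donor neighborhoods differ.
    def _set_base(tx_index: int, offset: int, base: str) -> None:
        s0, e0 = ordered[tx_index]
        if e0 - s0 < 2:
            return
        if strand == "+":
            gpos = s0 + offset if offset >= 0 else e0 + offset
            genome_arr[gpos] = base
        else:
            gpos = e0 - 1 - offset if offset >= 0 else s0 - 1 - offset
            genome_arr[gpos] = reverse_complement(base)

    for j, tx_index in enumerate(range(3, min(7, n_exons))):
        _set_base(tx_index, 0, "ACGT"[j])
    for j, tx_index in enumerate(range(2, min(6, n_exons))):
        _set_base(tx_index, -1, "ACGT"[j])

    genome = "".join(genome_arr)
    exons = []
    for i, (s0, e0) in enumerate(ordered):
        seq = genome[s0:e0]
        if strand == "-":
            seq = reverse_complement(seq)
        exons.append(
            Exon(
                exon_id=f"E{i + 1}",
                chrom=chrom,
                start=s0 + 1,
                end=e0,
                strand=strand,
                sequence=seq,
            )
        )
    model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(exons))
    lines = [f">{chrom}"]
    lines += [genome[i : i + 60] for i in range(0, genome_len, 60)]
    return model, "\n".join(lines) + "\n"


def _isoform_exon_indices(model: GeneModel, label: str) -> list[int]:
    _check_label(label)
    if len(model.exons) < 7:
        raise ValueError("model too short for CD45-like isoform labels")
    alt = set(_ALT_POSITIONS.values())
    included = set() if label == "RO" else {_ALT_POSITIONS[c] for c in label[1:]}
    return [i for i in range(len(model.exons)) if i not in alt or i in included]


def isoform_sequence(model: GeneModel, label: str) -> str:
    """Spliced transcript sequence for an isoform label (e.g. "RABC", "RO")."""
    parts = []
    for i in _isoform_exon_indices(model, label):
        seq = model.exons[i].sequence
        if seq is None:
            raise ValueError("model must carry sequences")
        parts.append(seq)
    return "".join(parts)


@dataclass
class TruthTable:
    """Ground truth of a simulation: molecule labels and expected counts."""

    molecules: dict[tuple[str, str], str]  # (barcode, umi) -> isoform label
    barcodes: list[str]

    def feature_set(self, barcode: str, umi: str) -> frozenset[str]:
        return label_features(self.molecules[(barcode, umi)])

    def expected_counts(self, feature_names=("RA", "RB", "RC", "RO")) -> pd.DataFrame:
        """Per-cell per-feature UMI counts under union-then-split weighting.

        Each molecule contributes 1/|F| to each feature of its label's set.
        """
        frame = pd.DataFrame(
            0.0, index=list(feature_names), columns=self.barcodes
        )
        for (barcode, _umi), label in self.molecules.items():
            feats = label_features(label)
            w = 1.0 / len(feats)
            for f in feats:
                frame.loc[f, barcode] += w
        return frame

    def to_json(self) -> str:
        return json.dumps(
            {
                "barcodes": self.barcodes,
                "molecules": [
                    {"barcode": bc, "umi": umi, "label": label}
                    for (bc, umi), label in sorted(self.molecules.items())
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        payload = json.loads(text)
        return cls(
            molecules={
                (m["barcode"], m["umi"]): m["label"] for m in payload["molecules"]
            },
            barcodes=payload["barcodes"],
        )


def make_cell_profiles(
    n_cells: int,
    labels=("RABC", "RA", "RB", "RO"),
    umis_per_cell: tuple[int, int] = (3, 8),
    seed: int = 0,
) -> dict[str, dict[str, int]]:
    """One isoform profile per cell, cycled over ``labels``.

    UMI counts per cell are drawn uniformly from ``umis_per_cell``.
    """
    rng = np.random.default_rng(seed)
    profiles: dict[str, dict[str, int]] = {}
    for i, barcode in enumerate(make_barcodes(n_cells)):
        label = labels[i % len(labels)]
        profiles[barcode] = {label: int(rng.integers(umis_per_cell[0], umis_per_cell[1] + 1))}
    return profiles


def _transcript_layout(model: GeneModel, label: str) -> list[tuple[int, int, int, int]]:
    """(transcript_offset, transcript_end, genomic_start0, genomic_end0) per exon."""
    layout = []
    offset = 0
    for i in _isoform_exon_indices(model, label):
        e = model.exons[i]
        layout.append((offset, offset + e.length, e.start0, e.end0))
        offset += e.length
    return layout


def _lift_to_genome(
    layout, strand: str, s: int, read_len: int
) -> list[tuple[int, int]]:
    """Genomic aligned blocks (ascending, 0-based half-open) of transcript window [s, s+R)."""
    blocks = []
    for t0, t1, g0, g1 in layout:
        a, b = max(s, t0), min(s + read_len, t1)
        if a >= b:
            continue
        if strand == "+":
            blocks.append((g0 + (a - t0), g0 + (b - t0)))
        else:
            blocks.append((g1 - (b - t0), g1 - (a - t0)))
    return sorted(blocks)


def _cigar_string(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _feature_windows(
    model: GeneModel, label: str, read_len: int, t: int
) -> dict[str, tuple[int, int]]:
    """Valid read-start ranges (inclusive) giving >= t overlap per feature."""
    layout = _transcript_layout(model, label)
    total = layout[-1][1]
    indices = _isoform_exon_indices(model, label)
    windows: dict[str, tuple[int, int]] = {}
    if label == "RO":
        junction = layout[indices.index(6)][0]  # transcript offset of exon 7
        lo, hi = junction - (read_len - t), junction - t
        windows["RO"] = (max(0, lo), min(total - read_len, hi))
    else:
        for letter, position in _ALT_POSITIONS.items():
            if position not in indices:
                continue
            fs, fe = layout[indices.index(position)][:2]
            lo, hi = fs - (read_len - t), fe - t
            windows[f"R{letter}"] = (max(0, lo), min(total - read_len, hi))
    for feature, (lo, hi) in windows.items():
        if lo > hi:
            raise ValueError(
                f"no informative read placement for {feature} at read_len {read_len}"
            )
    return windows


def simulate_reads(
    model: GeneModel,
    cell_profiles: dict[str, dict[str, int]],
    read_len: int = 98,
    error_rate: float = 0.0,
    seed: int = 0,
    reads_per_umi: int = 1,
    informative_overlap: int | None = None,
    antisense_fraction: float = 0.0,
    umi_len: int = 12,
) -> tuple[str, TruthTable]:
    """Simulate barcoded, UMI-tagged spliced reads as coordinate-sorted SAM.

    For each (cell, isoform, UMI) molecule, reads are drawn from the spliced
    transcript and lifted to the genome (N gaps across skipped introns).  With
    ``informative_overlap`` set, one read per feature of the molecule's label
    is placed so it overlaps that feature by at least that many bases — the
    regime where every molecule is fully recoverable.  Substitution errors are
    applied at ``error_rate``; everything is deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    # independent stream for substitution errors, so read placement is
    # identical across error rates at a fixed seed
    err_rng = np.random.default_rng((seed + 1) * 7919)
    genome_len = 0
    layouts: dict[str, list] = {}
    sequences: dict[str, str] = {}
    for label in {l for prof in cell_profiles.values() for l in prof}:
        layouts[label] = _transcript_layout(model, label)
        sequences[label] = isoform_sequence(model, label)
        if read_len > len(sequences[label]):
            raise ValueError(
                f"read_len {read_len} exceeds transcript length of {label}"
            )
        genome_len = max(genome_len, max(g1 for _, _, _, g1 in layouts[label]))

    molecules: dict[tuple[str, str], str] = {}
    sam_reads = []
    counter = 0
    for barcode in cell_profiles:
        umi_index = 0
        for label in sorted(cell_profiles[barcode]):
            layout = layouts[label]
            tseq = sequences[label]
            total = len(tseq)
            for _ in range(cell_profiles[barcode][label]):
                umi = _encode_index(umi_index, umi_len)
                umi_index += 1
                molecules[(barcode, umi)] = label
                if informative_overlap is not None:
                    windows = _feature_windows(
                        model, label, read_len, informative_overlap
                    )
                    starts = [
                        int(rng.integers(lo, hi + 1))
                        for _ in range(reads_per_umi)
                        for lo, hi in (windows[f] for f in sorted(windows))
                    ]
                else:
                    starts = [
                        int(rng.integers(0, total - read_len + 1))
                        for _ in range(reads_per_umi)
                    ]
                for s in starts:
                    seq = tseq[s : s + read_len]
                    if error_rate > 0:
                        seq = _mutate(seq, error_rate, err_rng)
                    blocks = _lift_to_genome(layout, model.strand, s, read_len)
                    if model.strand == "-":
                        seq = reverse_complement(seq)
                    flag = 0 if model.strand == "+" else 16
                    if antisense_fraction > 0 and rng.random() < antisense_fraction:
                        flag ^= 16
                        seq = reverse_complement(seq)
                    sam_reads.append(
                        (
                            blocks[0][0],
                            f"r{counter:07d}",
                            flag,
                            _cigar_string(blocks),
                            seq,
                            barcode,
                            umi,
                        )
                    )
                    counter += 1

    sam_reads.sort(key=lambda r: (r[0], r[1]))
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{model.chrom}\tLN:{genome_len + 500}",
    ]
    for pos0, qname, flag, cigar, seq, barcode, umi in sam_reads:
        lines.append(
            "\t".join(
                [
                    qname,
                    str(flag),
                    model.chrom,
                    str(pos0 + 1),
                    "255",
                    cigar,
                    "*",
                    "0",
                    "0",
                    seq,
                    "I" * len(seq),
                    "NH:i:1",
                    f"CB:Z:{barcode}",
                    f"UB:Z:{umi}",
                ]
            )
        )
    truth = TruthTable(molecules=molecules, barcodes=list(cell_profiles))
    return "\n".join(lines) + "\n", truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def write_fixture(
    out_dir,
    n_cells: int = 20,
    n_exons: int = 9,
    read_len: int = 98,
    seed: int = 0,
    informative_overlap: int | None = None,
    reads_per_umi: int = 2,
    error_rate: float = 0.0,
) -> dict[str, Path]:
    """Write a complete fixture (genome, GTF, SAM, truth, whitelist) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, fasta = make_toy_model(n_exons=n_exons, seed=seed)
    profiles = make_cell_profiles(n_cells, seed=seed)
    sam, truth = simulate_reads(
        model,
        profiles,
        read_len=read_len,
        seed=seed,
        reads_per_umi=reads_per_umi,
        informative_overlap=informative_overlap,
        error_rate=error_rate,
    )
    paths = {
        "genome": out / "genome.fa",
        "gtf": out / "annotation.gtf",
        "sam": out / "reads.sam",
        "truth": out / "truth.json",
        "whitelist": out / "whitelist.txt",
    }
    paths["genome"].write_text(fasta)
    paths["gtf"].write_text(model_to_gtf(model))
    paths["sam"].write_text(sam)
    paths["truth"].write_text(truth.to_json())
    paths["whitelist"].write_text("".join(f"{bc}\n" for bc in truth.barcodes))
    return paths
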