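"""Construction of the discriminating isoform reference.

The central idea: for every feature of interest — an alternative exon or an
exon-exon junction — emit synthetic reference sequences consisting of the
feature surrounded by *flanks strictly shorter than the read length*.  With
read length R and a minimum required feature overlap of k bases, each flank is
at most R - k long, so any length-R read that maps fully inside such a
sequence must overlap the feature by at least k bases (for junctions: straddle
the junction point with at least k bases on each side).  Reads mapping to the
reference therefore certify feature presence.

Which exons may surround a feature is declared by *transcript building rules*:
a ``follows`` adjacency (exon X may be immediately followed by exon Y in some
transcript).  Flank chains are enumerated exhaustively over this adjacency, so
every splice context a rule-consistent transcript can produce is represented
in the reference.

Rules file grammar (line-oriented, ``#`` comments)::

    feature RA exon E4
    feature RO junction E3 E7
    follows E3: E4,E5,E6,E7
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_model import Exon, GeneModel

__all__ = [
    "FeatureSpec",
    "BuildRules",
    "FlankedTranscript",
    "ReferenceSet",
    "parse_rules",
    "compute_flank_length",
    "enumerate_flank_chains",
    "build_reference",
    "write_reference",
    "default_ptprc_rules",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One discriminating feature: an alternative exon or a junction."""

    name: str
    kind: str  # "exon" | "junction"
    target: str | tuple[str, str]

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise ValueError(f"feature name must be non-empty without whitespace: {self.name!r}")
        if self.kind == "exon":
            if not isinstance(self.target, str):
                raise ValueError(f"feature {self.name}: exon target must be a single exon id")
        elif self.kind == "junction":
            if not (isinstance(self.target, tuple) and len(self.target) == 2):
                raise ValueError(f"feature {self.name}: junction target must be (left, right)")
        else:
            raise ValueError(f"feature {self.name}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class BuildRules:
    """Features plus the exon adjacency allowed in transcripts."""

    features: tuple[FeatureSpec, ...]
    follows: dict[str, tuple[str, ...]]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def validate(self, model: GeneModel) -> None:
        ids = set(model.exon_ids)
        seen = set()
        for feat in self.features:
            if feat.name in seen:
                raise ValueError(f"duplicate feature name {feat.name!r}")
            seen.add(feat.name)
            targets = (feat.target,) if feat.kind == "exon" else feat.target
            for t in targets:
                if t not in ids:
                    raise ValueError(f"feature {feat.name}: unknown exon id {t!r}")
            if feat.kind == "junction":
                left, right = feat.target
                if model.exon_index(left) >= model.exon_index(right):
                    raise ValueError(
                        f"feature {feat.name}: junction exons not in transcript order"
                    )
        for src, dsts in self.follows.items():
            if src not in ids:
                raise ValueError(f"follows: unknown exon id {src!r}")
            for dst in dsts:
                if dst not in ids:
                    raise ValueError(f"follows: unknown exon id {dst!r}")
                if model.exon_index(dst) <= model.exon_index(src):
                    raise ValueError(
                        f"follows: {src} -> {dst} violates transcript order"
                    )
        # strict downstream edges make the graph acyclic by construction


@dataclass(frozen=True)
class FlankedTranscript:
    """One reference sequence: a feature plus its flanking exon context.

    ``feature_start``/``feature_end`` delimit the feature half-open within
    ``sequence``; junctions have a zero-width interval at the flank boundary.
    """

    ref_id: str
    feature_name: str
    upstream_chain: tuple[str, ...]
    downstream_chain: tuple[str, ...]
    sequence: str
    feature_start: int
    feature_end: int

    def __post_init__(self) -> None:
        if not self.ref_id or any(c.isspace() for c in self.ref_id):
            raise ValueError(f"ref_id must be non-empty without whitespace: {self.ref_id!r}")
        if not (0 <= self.feature_start <= self.feature_end <= len(self.sequence)):
            raise ValueError(f"{self.ref_id}: feature interval outside sequence")


@dataclass(frozen=True)
class ReferenceSet:
    """All flanked reference sequences built for one (read_len, min_overlap)."""

    transcripts: tuple[FlankedTranscript, ...]
    read_len: int
    min_overlap: int

    def __post_init__(self) -> None:
        ids = [t.ref_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ref_id in reference set")

    @property
    def flank_len(self) -> int:
        return compute_flank_length(self.read_len, self.min_overlap)

    @property
    def feature_map(self) -> dict[str, str]:
        return {t.ref_id: t.feature_name for t in self.transcripts}

    @property
    def feature_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.feature_name, None)
        return tuple(seen)


def compute_flank_length(read_len: int, min_overlap: int) -> int:
    """Maximum flank length R - k guaranteeing a k-base feature overlap.

    A junction feature needs k bases on both sides of the junction point, so
    reads must satisfy R >= 2k.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if read_len < 2 * min_overlap:
        raise ValueError(
            f"read length {read_len} too short for min_overlap {min_overlap} "
            f"(requires read_len >= 2*min_overlap)"
        )
    return read_len - min_overlap


def parse_rules(path, model: GeneModel) -> BuildRules:
    """Parse a transcript-building-rules file and validate it against a model."""
    features: list[FeatureSpec] = []
    follows: dict[str, tuple[str, ...]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            if tokens[0] == "feature":
                name, kind = tokens[1], tokens[2]
                if kind == "exon":
                    features.append(FeatureSpec(name, "exon", tokens[3]))
                elif kind == "junction":
                    features.append(FeatureSpec(name, "junction", (tokens[3], tokens[4])))
                else:
                    raise ValueError(f"unknown feature kind {kind!r}")
            elif tokens[0] == "follows":
                head, _, tail = line.partition(":")
                src = head.split()[1]
                dsts = tuple(t.strip() for t in tail.split(",") if t.strip())
                if not dsts:
                    raise ValueError("follows line lists no successors")
                if src in follows:
                    raise ValueError(f"duplicate follows line for {src}")
                follows[src] = dsts
            else:
                raise ValueError(f"unknown directive {tokens[0]!r}")
        except (IndexError, ValueError) as err:
            raise ValueError(f"rules file line {lineno}: {err}") from None
    rules = BuildRules(features=tuple(features), follows=follows)
    rules.validate(model)
    return rules


def default_ptprc_rules(model: GeneModel) -> BuildRules:
    """The canonical CD45 rules for a PTPRC-like exon model.

    Features RA/RB/RC are the alternative exons at transcript positions 4/5/6;
    RO is the junction joining exon 3 directly to exon 7 (all three alternative
    exons skipped).  Alternative exons may be included or skipped in any
    combination; all other exons are constitutive.
    """
    if len(model.exons) < 7:
        raise ValueError(
            f"model too short for CD45 rules: {len(model.exons)} exons (need >= 7)"
        )
    ids = model.exon_ids
    e3, e4, e5, e6, e7 = ids[2], ids[3], ids[4], ids[5], ids[6]
    features = (
        FeatureSpec("RA", "exon", e4),
        FeatureSpec("RB", "exon", e5),
        FeatureSpec("RC", "exon", e6),
        FeatureSpec("RO", "junction", (e3, e7)),
    )
    follows: dict[str, tuple[str, ...]] = {}
    follows[ids[0]] = (ids[1],)
    follows[ids[1]] = (e3,)
    follows[e3] = (e4, e5, e6, e7)
    follows[e4] = (e5, e6, e7)
    follows[e5] = (e6, e7)
    follows[e6] = (e7,)
    for i in range(6, len(ids) - 1):
        follows[ids[i]] = (ids[i + 1],)
    rules = BuildRules(features=features, follows=follows)
    rules.validate(model)
    return rules


def _predecessors(follows: dict[str, tuple[str, ...]]) -> dict[str, tuple[str, ...]]:
    preds: dict[str, list[str]] = {}
    for src, dsts in follows.items():
        for dst in dsts:
            preds.setdefault(dst, []).append(src)
    return {k: tuple(v) for k, v in preds.items()}


def enumerate_flank_chains(
    rules: BuildRules,
    model: GeneModel,
    anchor_exon: str,
    side: str,
    flank_len: int,
) -> list[tuple[str, ...]]:
    """All flank chains next to ``anchor_exon`` (anchor excluded), 5'->3'.

    Chains follow the ``follows`` adjacency away from the anchor and stop once
    the accumulated exon sequence reaches ``flank_len`` bases or the gene ends.
    Chains that truncate to the same flank sequence are collapsed (distinct
    continuations beyond the truncation point are indistinguishable to any
    read of the stated length).
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    model.exon_index(anchor_exon)  # raises KeyError if absent
    neighbors = rules.follows if side == "downstream" else _predecessors(rules.follows)
    seqs = {e.exon_id: e.sequence for e in model.exons}
    if any(seqs[x] is None for x in model.exon_ids):
        raise ValueError("model must carry sequences to enumerate flank chains")

    chains: list[tuple[str, ...]] = []

    def walk(chain: tuple[str, ...], total: int) -> None:
        tip = chain[-1] if chain else anchor_exon
        nxt = neighbors.get(tip, ())
        if total >= flank_len or not nxt:
            chains.append(chain)
            return
        for n in nxt:
            walk(chain + (n,), total + len(seqs[n]))

    walk((), 0)
    if side == "upstream":
        chains = [tuple(reversed(c)) for c in chains]
    # collapse chains indistinguishable after truncation to flank_len
    deduped: list[tuple[str, ...]] = []
    seen: set[str] = set()
    for c in chains:
        flank = _flank_sequence(seqs, c, flank_len, side)
        if flank not in seen:
            seen.add(flank)
            deduped.append(c)
    return deduped


def _flank_sequence(
    seqs: dict[str, str | None], chain: tuple[str, ...], flank_len: int, side: str
) -> str:
    cat = "".join(seqs[x] for x in chain)  # type: ignore[misc]
    if side == "upstream":
        return cat[-flank_len:] if flank_len else ""
    return cat[:flank_len]


def _anchored_chains(
    rules: BuildRules,
    model: GeneModel,
    anchor: str,
    side: str,
    flank_len: int,
) -> list[tuple[str, ...]]:
    """Chains *including* the anchor exon, used for junction flanks."""
    anchor_len = len(model.exon(anchor).sequence or "")
    if anchor_len >= flank_len:
        return [(anchor,)]
    inner = enumerate_flank_chains(rules, model, anchor, side, flank_len - anchor_len)
    if side == "upstream":
        return [c + (anchor,) for c in inner]
    return [(anchor,) + c for c in inner]


def build_reference(
    model: GeneModel,
    rules: BuildRules,
    read_len: int,
    min_overlap: int = 1,
) -> ReferenceSet:
    """Build every flanked reference sequence for the declared features.

    For exon features the full exon sits between an upstream flank (the last
    ``flank_len`` bases of each enumerated upstream chain) and a downstream
    flank (the first ``flank_len`` bases of each downstream chain); every
    upstream x downstream chain combination yields one sequence.  Junction
    features abut the two flanks directly, anchored on the junction exons.
    Sequences identical after truncation are emitted once.
    """
    rules.validate(model)
    flank_len = compute_flank_length(read_len, min_overlap)
    seqs = {e.exon_id: e.sequence for e in model.exons}
    if any(v is None for v in seqs.values()):
        raise ValueError("model must carry sequences to build a reference")

    transcripts: list[FlankedTranscript] = []
    seen_sequences: set[str] = set()
    for feat in rules.features:
        if feat.kind == "exon":
            core = seqs[feat.target]  # type: ignore[index]
            if len(core) < min_overlap:
                raise ValueError(
                    f"feature {feat.name}: exon {feat.target} shorter than "
                    f"min_overlap {min_overlap}; the overlap guarantee cannot hold"
                )
            up_chains = enumerate_flank_chains(rules, model, feat.target, "upstream", flank_len)
            dn_chains = enumerate_flank_chains(rules, model, feat.target, "downstream", flank_len)
        else:
            left, right = feat.target  # type: ignore[misc]
            core = ""
            up_chains = _anchored_chains(rules, model, left, "upstream", flank_len)
            dn_chains = _anchored_chains(rules, model, right, "downstream", flank_len)
        if not up_chains or not dn_chains:
            raise ValueError(f"feature {feat.name}: no valid flank chains")
        for uc in up_chains:
            up = _flank_sequence(seqs, uc, flank_len, "upstream")
            for dc in dn_chains:
                dn = _flank_sequence(seqs, dc, flank_len, "downstream")
                sequence = up + core + dn
                if sequence in seen_sequences:
                    continue
                seen_sequences.add(sequence)
                ref_id = "|".join(
                    [feat.name, "-".join(uc) or ".", "-".join(dc) or "."]
                )
                transcripts.append(
                    FlankedTranscript(
                        ref_id=ref_id,
                        feature_name=feat.name,
                        upstream_chain=uc,
                        downstream_chain=dc,
                        sequence=sequence,
                        feature_start=len(up),
                        feature_end=len(up) + len(core),
                    )
                )
    return ReferenceSet(
        transcripts=tuple(transcripts), read_len=read_len, min_overlap=min_overlap
    )


def write_reference(refset: ReferenceSet, fasta_path, t2g_path) -> None:
    """Write the reference FASTA plus the ref_id -> feature_name map (TSV).

    Output is deterministic: records appear in construction order.
    """
    if not refset.transcripts:
        raise ValueError("empty reference set")
    records = [
        SeqRecord(Seq(t.sequence), id=t.ref_id, description="")
        for t in refset.transcripts
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(t2g_path, "w") as fh:
        for t in refset.transcripts:
            fh.write(f"{t.ref_id}\t{t.feature_name}\n")
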