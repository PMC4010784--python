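"""Exact and bounded-mismatch tag placement plus the hierarchical triage.

Substitution-only alignment on both strands. Coordinates are 0-based
half-open on the forward reference text; minus-strand hits mean the
reverse complement of the tag matches the forward text at [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .sequtils import revcomp

DEFAULT_SEED_LENGTH = 10
TRNA_RDNA_MISMATCH = 3
RELAXED_MISMATCH = 3

CATEGORIES = (
    "trna_rdna",
    "genome_perfect",
    "genome_mismatch",
    "chloroplast",
    "mitochondrion",
    "unmapped",
)


class AlignmentHit(NamedTuple):
    tag_sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int


_PAD = 64  # spacer longer than any query, bytes never matching ACGT


class SeedIndex:
    """Exact k-mer index over a reference set, with one concatenated
    zero-padded byte array for the vectorised mismatch scan."""

    def __init__(self, references: dict[str, str], seed_length: int = DEFAULT_SEED_LENGTH):
        if not references:
            raise ValueError("empty reference set")
        self.references = {name: seq.upper() for name, seq in references.items()}
        self.seed_length = seed_length
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        parts, bounds, offset = [], [], 0
        for name, seq in self.references.items():
            parts.append(np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
            parts.append(np.zeros(_PAD, dtype=np.uint8))
            bounds.append((offset, offset + len(seq), name))
            offset += len(seq) + _PAD
            for pos in range(len(seq) - seed_length + 1):
                self._seeds.setdefault(seq[pos : pos + seed_length], []).append((name, pos))
        self._concat = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self._text = "".join(
            seq + "\0" * _PAD for seq in self.references.values()
        )
        self._starts = np.array([b[0] for b in bounds])
        self._bounds = bounds
        self._chunk_tables: dict[int, dict[str, np.ndarray]] = {}

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._seeds.get(kmer, [])

    def chunk_table(self, q: int) -> dict[str, np.ndarray]:
        """Positions of every q-mer in the concatenated text (built lazily)."""
        if q not in self._chunk_tables:
            table: dict[str, list[int]] = {}
            text = self._text
            for start, end, _name in self._bounds:
                for pos in range(start, end - q + 1):
                    table.setdefault(text[pos : pos + q], []).append(pos)
            self._chunk_tables[q] = {
                k: np.array(v, dtype=np.int64) for k, v in table.items()
            }
        return self._chunk_tables[q]

    def locate(self, concat_pos: int, length: int) -> tuple[str, int] | None:
        """Map a concatenated-array offset back to (contig, position); None
        when the window crosses a contig boundary."""
        i = int(np.searchsorted(self._starts, concat_pos, side="right")) - 1
        start, end, name = self._bounds[i]
        if concat_pos + length <= end:
            return name, concat_pos - start
        return None


def build_index(references: dict[str, str], seed_length: int = DEFAULT_SEED_LENGTH) -> SeedIndex:
    return SeedIndex(references, seed_length=seed_length)


def _exact_placements(index: SeedIndex, query: str) -> list[tuple[str, int]]:
    k = index.seed_length
    if len(query) < k:
        raise ValueError(f"query shorter than seed length {k}")
    out = []
    for name, pos in index.lookup(query[:k]):
        ref = index.references[name]
        if ref[pos : pos + len(query)] == query:
            out.append((name, pos))
    return out


def _scan_placements(index: SeedIndex, query: str, max_mismatch: int) -> list[tuple[str, int, int]]:
    """Placements with <= max_mismatch substitutions on the forward text.

    Pigeonhole seeding: the query is split into max_mismatch + 1 disjoint
    chunks, one of which must match exactly; chunk hits give candidate
    starts that are verified by direct vectorised comparison. Falls back to
    a full sliding-window scan when the chunks would be shorter than 3 nt.
    """
    qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    arr = index._concat
    length = len(qarr)
    if len(arr) < length:
        return []
    parts = max_mismatch + 1
    chunk = length // parts
    if chunk >= 3:
        table = index.chunk_table(chunk)
        cands = []
        for c in range(parts):
            off = c * chunk
            hits = table.get(query[off : off + chunk])
            if hits is not None:
                cands.append(hits - off)
        if not cands:
            return []
        starts = np.unique(np.concatenate(cands))
        starts = starts[(starts >= 0) & (starts + length <= len(arr))]
        if len(starts) == 0:
            return []
        windows = arr[starts[:, None] + np.arange(length)]
        mism = (windows != qarr).sum(axis=1)
        keep = mism <= max_mismatch
        positions = starts[keep]
        counts = mism[keep]
    else:
        windows = np.lib.stride_tricks.sliding_window_view(arr, length)
        mism = (windows != qarr).sum(axis=1)
        positions = np.flatnonzero(mism <= max_mismatch)
        counts = mism[positions]
    out = []
    for pos, mm in zip(positions, counts):
        placed = index.locate(int(pos), length)
        if placed is not None:
            out.append((placed[0], placed[1], int(mm)))
    return out


def align(tags: Iterable[str], index: SeedIndex, max_mismatch: int = 0) -> dict[str, list[AlignmentHit]]:
    """All placements with <= max_mismatch substitutions, both strands.

    The exact path (max_mismatch=0) goes through the seed index and is
    string-verified; mismatch budgets use a full vectorised Hamming scan.
    """
    if max_mismatch not in (0, 1, 2, 3):
        raise ValueError("max_mismatch must be in 0..3")
    hits: dict[str, list[AlignmentHit]] = {}
    for tag in tags:
        found: list[AlignmentHit] = []
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            if max_mismatch == 0:
                for name, pos in _exact_placements(index, query):
                    found.append(AlignmentHit(tag, name, pos, pos + len(tag), strand, 0))
            else:
                for name, pos, mm in _scan_placements(index, query, max_mismatch):
                    found.append(AlignmentHit(tag, name, pos, pos + len(tag), strand, mm))
        if found:
            hits[tag] = sorted(found, key=lambda h: (h.chrom, h.start, h.strand))
    return hits


@dataclass
class ReferenceBundle:
    trna: dict[str, str]
    rdna: dict[str, str]
    genome: dict[str, str]
    chloroplast: dict[str, str]
    mitochondrion: dict[str, str]

    def require(self, stage: str) -> dict[str, str]:
        ref = getattr(self, stage)
        if not ref:
            raise ValueError(f"missing reference set for stage: {stage}")
        return ref


@dataclass
class TriageResult:
    category: dict[str, str]  # tag sequence -> category
    genome_hits: dict[str, list[AlignmentHit]]  # perfect hits only
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def tags_in(self, category: str) -> list[str]:
        return [t for t, c in self.category.items() if c == category]


def hierarchical_filter(
    tag_abundance: dict[str, dict[str, int]],
    references: ReferenceBundle,
    *,
    relaxed_mm: int = RELAXED_MISMATCH,
    trna_rdna_mm: int = TRNA_RDNA_MISMATCH,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> TriageResult:
    """Triage tags through the alignment cascade.

    Order: tRNA/rDNA (<= trna_rdna_mm, removed) -> genome perfect (kept for
    block building) -> genome relaxed (reported only) -> chloroplast ->
    mitochondrion -> unmapped. `tag_abundance` maps library -> tag -> count.
    """
    all_tags = sorted({t for lib in tag_abundance.values() for t in lib})
    category: dict[str, str] = {}
    genome_hits: dict[str, list[AlignmentHit]] = {}

    decoy_ref = dict(references.require("trna"))
    decoy_ref.update(references.require("rdna"))
    decoy_index = build_index(decoy_ref, seed_length)
    decoy_hits = align(all_tags, decoy_index, trna_rdna_mm)
    remaining = []
    for tag in all_tags:
        if tag in decoy_hits:
            category[tag] = "trna_rdna"
        else:
            remaining.append(tag)

    genome_index = build_index(references.require("genome"), seed_length)
    still = []
    perfect = align(remaining, genome_index, 0)
    for tag in remaining:
        if tag in perfect:
            category[tag] = "genome_perfect"
            genome_hits[tag] = perfect[tag]
        else:
            still.append(tag)

    relaxed = align(still, genome_index, relaxed_mm) if relaxed_mm > 0 else {}
    rest = []
    for tag in still:
        if tag in relaxed:
            category[tag] = "genome_mismatch"
        else:
            rest.append(tag)

    for stage, cat in (("chloroplast", "chloroplast"), ("mitochondrion", "mitochondrion")):
        ref = references.require(stage)
        idx = build_index(ref, seed_length)
        nxt = []
        stage_hits = align(rest, idx, relaxed_mm)
        for tag in rest:
            if tag in stage_hits:
                category[tag] = cat
            else:
                nxt.append(tag)
        rest = nxt
    for tag in rest:
        category[tag] = "unmapped"

    rows = []
    for lib, tags in tag_abundance.items():
        totals = {c: 0 for c in CATEGORIES}
        ntags = {c: 0 for c in CATEGORIES}
        for tag, count in tags.items():
            cat = category[tag]
            totals[cat] += count
            ntags[cat] += 1
        lib_total = sum(totals.values())
        for cat in CATEGORIES:
            rows.append(
                {
                    "library_id": lib,
                    "category": cat,
                    "reads": totals[cat],
                    "tags": ntags[cat],
                    "fraction": totals[cat] / lib_total if lib_total else 0.0,
                }
            )
    return TriageResult(category=category, genome_hits=genome_hits, summary=pd.DataFrame(rows))
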