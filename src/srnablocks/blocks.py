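"""Proximity-based block building and weighted block quantification."""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aligner import AlignmentHit

DEFAULT_GAP = 100
SIZE_RANGE = range(17, 37)


@dataclass(frozen=True)
class Block:
    block_id: str
    chrom: str
    start: int
    end: int


def build_blocks(hits: Iterable[AlignmentHit], gap: int = DEFAULT_GAP) -> list[Block]:
    """Merge alignment intervals separated by <= gap nt into blocks.

    Strand-agnostic; block span runs from the leftmost member start to the
    rightmost member end. Blocks are returned sorted by (chrom, start) and
    numbered in that order.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append((h.start, h.end))
    blocks: list[Block] = []
    n = 0
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        cur_start, cur_end = ivals[0]
        for start, end in ivals[1:]:
            if start - cur_end <= gap:
                cur_end = max(cur_end, end)
            else:
                blocks.append(Block(f"block_{n:06d}", chrom, cur_start, cur_end))
                n += 1
                cur_start, cur_end = start, end
        blocks.append(Block(f"block_{n:06d}", chrom, cur_start, cur_end))
        n += 1
    return blocks


class BlockLocator:
    """Maps a placement to its containing block by binary search."""

    def __init__(self, blocks: Sequence[Block]):
        self._starts: dict[str, list[int]] = {}
        self._blocks: dict[str, list[Block]] = {}
        for b in blocks:
            self._starts.setdefault(b.chrom, []).append(b.start)
            self._blocks.setdefault(b.chrom, []).append(b)

    def find(self, chrom: str, start: int, end: int) -> Block | None:
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            return None
        b = self._blocks[chrom][i]
        if start >= b.start and end <= b.end:
            return b
        return None


def weighted_counts(
    blocks: Sequence[Block],
    genome_hits: dict[str, list[AlignmentHit]],
    tag_abundance: dict[str, dict[str, int]],
) -> pd.DataFrame:
    """Per-block, per-library weighted counts.

    Each of a tag's k genome-perfect placements contributes abundance/k to
    its containing block, so a multi-mapping tag is never over-counted; the
    grand total equals the total genome-perfect abundance.
    """
    locator = BlockLocator(blocks)
    libs = sorted(tag_abundance)
    block_ids = [b.block_id for b in blocks]
    row_of = {bid: i for i, bid in enumerate(block_ids)}
    acc = np.zeros((len(blocks), len(libs)), dtype=float)
    for tag, hits in genome_hits.items():
        k = len(hits)
        counts = np.array([tag_abundance[lib].get(tag, 0) for lib in libs], dtype=float)
        if not counts.any():
            continue
        share = counts / k
        for h in hits:
            block = locator.find(h.chrom, h.start, h.end)
            assert block is not None, "placement outside every block"
            acc[row_of[block.block_id]] += share
    mat = pd.DataFrame(acc, index=block_ids, columns=libs)
    mat.index.name = "block_id"
    return mat


def block_members(
    blocks: Sequence[Block], genome_hits: dict[str, list[AlignmentHit]]
) -> dict[str, list[AlignmentHit]]:
    """Placements grouped by containing block id."""
    locator = BlockLocator(blocks)
    members: dict[str, list[AlignmentHit]] = {b.block_id: [] for b in blocks}
    for hits in genome_hits.values():
        for h in hits:
            block = locator.find(h.chrom, h.start, h.end)
            assert block is not None, "placement outside every block"
            members[block.block_id].append(h)
    return members


@dataclass
class SizeProfile:
    shares: pd.Series  # fraction of abundance per length, index 17..36
    abundances: pd.Series
    ratio_21_24: float | None  # None when the 24-nt class is empty


def size_profile(tags: dict[str, int]) -> SizeProfile:
    """Per-length abundance shares (17-36 nt) and the 21:24 ratio."""
    abund = pd.Series(0.0, index=list(SIZE_RANGE))
    for seq, count in tags.items():
        if len(seq) in abund.index:
            abund[len(seq)] += count
    total = abund.sum()
    shares = abund / total if total > 0 else abund * 0.0
    ratio = None
    if abund[24] > 0:
        ratio = float(abund[21] / abund[24])
    return SizeProfile(shares=shares, abundances=abund, ratio_21_24=ratio)


def size_profiles(tag_abundance: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Share matrix (length x library) for reporting."""
    cols = {}
    for lib in sorted(tag_abundance):
        cols[lib] = size_profile(tag_abundance[lib]).shares
    df = pd.DataFrame(cols)
    df.index.name = "length"
    return df


def rpm(counts: pd.DataFrame | pd.Series, totals: pd.Series | float) -> pd.DataFrame | pd.Series:
    """Reads-per-million scaling (reporting and the DE prefilter only)."""
    return counts * 1e6 / totals
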