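"""Read collapsing, size selection and abundance-ranked error correction.

The error-correction step is a deterministic stand-in for frequency-based
clustering: tags are visited in increasing abundance order and merged into
a strictly more abundant same-length parent within the mismatch budget,
repeated to fixpoint. Total abundance is conserved exactly.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, NamedTuple

from .sequtils import hamming, is_acgt

log = logging.getLogger(__name__)

MIN_LENGTH = 17
MAX_LENGTH = 35


class UniqueTag(NamedTuple):
    sequence: str
    abundance: int
    library_id: str


def collapse_reads(reads: Iterable[str]) -> dict[str, int]:
    """Collapse reads to unique sequences with counts.

    Reads containing characters outside ACGT (including N) are dropped and
    the dropped count is logged. Total retained abundance equals the number
    of retained reads.
    """
    tags: Counter[str] = Counter()
    dropped = 0
    for read in reads:
        seq = read.upper()
        if not is_acgt(seq):
            dropped += 1
            continue
        tags[seq] += 1
    if dropped:
        log.info("collapse_reads: dropped %d reads with non-ACGT characters", dropped)
    return dict(tags)


def length_filter(
    tags: dict[str, int], min_len: int = MIN_LENGTH, max_len: int = MAX_LENGTH
) -> dict[str, int]:
    """Keep tags with min_len <= length <= max_len (defaults 17-35 nt)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return {seq: n for seq, n in tags.items() if min_len <= len(seq) <= max_len}


def _single_mismatch_neighbors(seq: str):
    for i, orig in enumerate(seq):
        for base in "ACGT":
            if base != orig:
                yield seq[:i] + base + seq[i + 1 :]


def _one_pass(tags: dict[str, int], max_mismatch: int) -> tuple[dict[str, int], bool]:
    current = dict(tags)
    # children visited in increasing abundance (ties: lexicographic)
    order = sorted(current, key=lambda s: (current[s], s))
    changed = False
    for child in order:
        child_count = current.get(child)
        if child_count is None:
            continue
        if max_mismatch == 1:
            parents = [
                (1, p)
                for p in _single_mismatch_neighbors(child)
                if current.get(p, 0) > child_count
            ]
        else:
            parents = [
                (hamming(child, p), p)
                for p in current
                if len(p) == len(child)
                and p != child
                and current[p] > child_count
                and hamming(child, p) <= max_mismatch
            ]
        if not parents:
            continue
        dmin = min(d for d, _ in parents)
        best = max(
            (p for d, p in parents if d == dmin),
            key=lambda p: (current[p], [-ord(c) for c in p]),
        )
        current[best] += child_count
        del current[child]
        changed = True
    return current, changed


def error_correct(tags: dict[str, int], max_mismatch: int = 1) -> dict[str, int]:
    """Merge low-abundance tags into more abundant same-length parents.

    Each pass merges one level; passes repeat until no merge occurs, making
    the operation idempotent. Parent choice: minimal distance, then highest
    abundance, then lexicographically smallest sequence.
    """
    current = dict(tags)
    while True:
        current, changed = _one_pass(current, max_mismatch)
        if not changed:
            return current


def preprocess_library(
    reads: Iterable[str],
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
    max_mismatch: int = 1,
) -> dict[str, int]:
    """collapse -> length filter -> error correction for one library."""
    return error_correct(
        length_filter(collapse_reads(reads), min_len, max_len), max_mismatch
    )
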