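"""Small sequence helpers shared across the package.

All sequences are stored in the DNA alphabet (uppercase ACGT); U is
converted to T on input where relevant.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte encoding used for vectorised scans
_ENC = {c: i for i, c in enumerate("ACGT")}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_acgt(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as uint8 codes 0..3 for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. random DNA with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join("ACGT"[c] for c in codes)


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide composition (Altschul-Erickson).

    Builds the dinucleotide multigraph, fixes a random last-edge tree oriented
    toward the terminal vertex, shuffles the remaining out-edges and walks the
    resulting Eulerian path. Sequences shorter than 3 nt are returned as-is.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    start, terminal = seq[0], seq[-1]
    vertices = list(edges)
    # choose one random "last edge" per non-terminal vertex such that every
    # vertex reaches the terminal through last edges (tree condition)
    while True:
        last = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices
            if v != terminal
        }
        ok = True
        for v in last:
            node, seen = v, set()
            while node != terminal and node in last:
                if node in seen:
                    break
                seen.add(node)
                node = last[node]
            if node != terminal and node not in edges:
                # dead-end vertex without out-edges can only be the terminal
                ok = False
                break
            if node != terminal:
                ok = False
                break
        if ok:
            break
    order: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in last:
            rest.remove(last[v])
        rng.shuffle(rest)
        if v in last:
            rest.append(last[v])
        order[v] = rest
    ptr = {v: 0 for v in order}
    out = [start]
    node = start
    for _ in range(len(seq) - 1):
        nxt = order[node][ptr[node]]
        ptr[node] += 1
        out.append(nxt)
        node = nxt
    return "".join(out)
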