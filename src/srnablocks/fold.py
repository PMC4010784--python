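"""Secondary-structure folding backends.

The baseline backend is a Nussinov-style dynamic program that minimises a
simple additive pair-energy model (GC = -3, AU = -2, GU = -1 kcal/mol,
minimum hairpin loop of 3 unpaired bases). It is deliberately
dependency-free and deterministic; a thermodynamic backend ("vienna") is
used instead when the ViennaRNA python bindings are importable.
"""

from __future__ import annotations

import numpy as np

MIN_LOOP = 3
_BIG = 10_000

# codes A=0 C=1 G=2 T/U=3
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
_CODE[ord("U")] = 3

_PAIR = np.full((4, 4), _BIG, dtype=np.int32)
_PAIR[0, 3] = _PAIR[3, 0] = -2  # A:U
_PAIR[1, 2] = _PAIR[2, 1] = -3  # G:C
_PAIR[2, 3] = _PAIR[3, 2] = -1  # G:U

try:  # optional JIT for the O(n^3) fill
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGTU")
    return codes.astype(np.int64)


def _fill_numpy(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    e = np.zeros((n, n), dtype=np.int32)
    for d in range(MIN_LOOP + 1, n):
        i = np.arange(n - d)
        j = i + d
        best = np.minimum(e[i + 1, j], e[i, j - 1])
        pe = _PAIR[codes[i], codes[j]]
        cand = e[i + 1, j - 1] + pe
        best = np.where(pe < _BIG, np.minimum(best, cand), best)
        for t in range(1, d - 1):
            np.minimum(best, e[i, i + t] + e[i + t + 1, j], out=best)
        e[i, j] = best
    return e


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _fill_jit(codes, pair, min_loop):  # pragma: no cover - jitted
        n = len(codes)
        e = np.zeros((n, n), dtype=np.int32)
        for d in range(min_loop + 1, n):
            for i in range(n - d):
                j = i + d
                best = e[i + 1, j]
                if e[i, j - 1] < best:
                    best = e[i, j - 1]
                pe = pair[codes[i], codes[j]]
                if pe < 9999:
                    cand = e[i + 1, j - 1] + pe
                    if cand < best:
                        best = cand
                for t in range(1, d - 1):
                    cand = e[i, i + t] + e[i + t + 1, j]
                    if cand < best:
                        best = cand
                e[i, j] = best
        return e


def _fill(codes: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA:
        return _fill_jit(codes, _PAIR, MIN_LOOP)
    return _fill_numpy(codes)


def _traceback(e: np.ndarray, codes: np.ndarray) -> str:
    n = len(codes)
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        v = e[i, j]
        if v == e[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if v == e[i, j - 1]:
            stack.append((i, j - 1))
            continue
        pe = _PAIR[codes[i], codes[j]]
        if pe < _BIG and v == e[i + 1, j - 1] + pe:
            struct[i], struct[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for t in range(1, j - i - 1):
            if v == e[i, i + t] + e[i + t + 1, j]:
                stack.append((i, i + t))
                stack.append((i + t + 1, j))
                break
        else:  # pragma: no cover - recurrence guarantees a branch
            raise AssertionError("traceback failed")
    return "".join(struct)


def fold_baseline(seq: str) -> tuple[str, float]:
    """Minimum-energy structure under the baseline pair-energy model.

    Returns (dot-bracket structure, energy in kcal/mol; 0.0 if no pairs).
    """
    if len(seq) < MIN_LOOP + 2:
        return "." * len(seq), 0.0
    codes = _encode(seq)
    e = _fill(codes)
    return _traceback(e, codes), float(e[0, len(seq) - 1])


def structure_energy(seq: str, structure: str) -> float:
    """Recompute the baseline energy of a dot-bracket structure."""
    if len(seq) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    codes = _encode(seq)
    total = 0
    stack: list[int] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            i = stack.pop()
            if idx - i <= MIN_LOOP:
                raise ValueError("pair violates minimum loop")
            pe = _PAIR[codes[i], codes[idx]]
            if pe >= _BIG:
                raise ValueError(f"non-canonical pair at {i},{idx}")
            total += int(pe)
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return float(total)


def fold_vienna(seq: str, temperature: float = 25.0) -> tuple[str, float]:
    """MFE fold via the ViennaRNA bindings (optional backend)."""
    import RNA  # noqa: PLC0415 - optional dependency

    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(seq.upper().replace("T", "U"), md)
    structure, mfe = fc.mfe()
    return structure, float(mfe)


def fold(seq: str, backend: str = "baseline", temperature: float = 25.0) -> tuple[str, float]:
    """Fold a window, dispatching to the requested backend."""
    if backend == "baseline":
        return fold_baseline(seq)
    if backend == "vienna":
        return fold_vienna(seq, temperature=temperature)
    raise ValueError(f"unknown fold backend: {backend!r}")


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position, -1 when unpaired."""
    table = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            i = stack.pop()
            table[i] = idx
            table[idx] = i
    if stack:
        raise ValueError("unbalanced structure")
    return table
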