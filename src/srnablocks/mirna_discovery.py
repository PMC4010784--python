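"""Novel-miRNA discovery: candidate selection, window folding and the
three goodness-of-fold criteria plus the free-energy gate.

A candidate is a (key sequence, genomic placement) pair. The 170-nt
strand-specific window around the placement is folded and the resulting
structure is judged on:

  (i)   more than 75% of the key-sequence bases paired;
  (ii)  the star span no longer than 1.5x the key length;
  (iii) key and star separated by at least 20 nt, and no base within
        10 nt of the key ends pairing into the star arm;
  (dG)  folding energy at or below the threshold (default -40 kcal/mol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import fold as _fold
from .aligner import AlignmentHit
from .sequtils import revcomp

log = logging.getLogger(__name__)

WINDOW_LENGTH = 170
DG_THRESHOLD = -40.0
MAX_LOCI = 20
FLANK_GUARD = 10
MIN_SEPARATION = 20


@dataclass
class HairpinCandidate:
    key_sequence: str
    window_sequence: str
    chrom: str
    window_start: int
    window_end: int
    strand: str
    structure: str = ""
    delta_g: float = 0.0
    paired_fraction: float = 0.0
    star_span_length: int = 0
    separation: int = -1
    criteria: dict = field(default_factory=dict)
    verdict: bool = False


@dataclass
class MirnaCall:
    candidate: HairpinCandidate
    status: str  # "known" | "novel"
    matched_reference_id: str | None
    size_class: int


def candidate_loci(
    genome_hits: dict[str, list[AlignmentHit]], max_loci: int = MAX_LOCI
) -> list[tuple[str, AlignmentHit]]:
    """One candidate per placement, for tags mapping to <= max_loci loci."""
    out: list[tuple[str, AlignmentHit]] = []
    for seq in sorted(genome_hits):
        hits = genome_hits[seq]
        if 1 <= len(hits) <= max_loci:
            out.extend((seq, h) for h in hits)
    return out


def extract_window(
    genome: dict[str, str], placement: AlignmentHit, length: int = WINDOW_LENGTH
) -> tuple[str, tuple[str, int, int, str]] | None:
    """Strand-specific window of exactly `length` nt centred on the placement.

    The window is shifted inward at contig edges; contigs shorter than the
    window yield None (candidate rejected, not an error).
    """
    chrom_seq = genome[placement.chrom]
    if len(chrom_seq) < length:
        return None
    mid = (placement.start + placement.end) // 2
    start = mid - length // 2
    start = max(0, min(start, len(chrom_seq) - length))
    end = start + length
    window = chrom_seq[start:end]
    if placement.strand == "-":
        window = revcomp(window)
    return window, (placement.chrom, start, end, placement.strand)


def evaluate_hairpin(
    candidate: HairpinCandidate,
    dg_threshold: float = DG_THRESHOLD,
) -> HairpinCandidate:
    """Apply the goodness-of-fold criteria to a folded candidate in place."""
    window, key = candidate.window_sequence, candidate.key_sequence
    key_start = window.find(key)  # most 5' occurrence
    assert key_start >= 0, "key sequence not inside window"
    key_end = key_start + len(key)

    table = _fold.pair_table(candidate.structure)
    partners = [int(table[i]) for i in range(key_start, key_end) if table[i] >= 0]
    paired_fraction = len(partners) / len(key)
    candidate.paired_fraction = paired_fraction
    crit_i = paired_fraction > 0.75

    if partners:
        star_lo, star_hi = min(partners), max(partners)
        star_span = star_hi - star_lo + 1
        crit_ii = star_span <= 1.5 * len(key)
        # separation between the key interval and the star interval
        if star_lo > key_end - 1:
            separation = star_lo - key_end
        elif star_hi < key_start:
            separation = key_start - star_hi - 1
        else:
            separation = 0  # overlapping spans
        guard_lo = max(0, key_start - FLANK_GUARD)
        guard_hi = min(len(window), key_end + FLANK_GUARD)
        guarded_ok = True
        for pos in range(guard_lo, guard_hi):
            p = int(table[pos])
            if p >= 0 and star_lo <= p <= star_hi and not (key_start <= pos < key_end):
                guarded_ok = False
                break
        crit_iii = separation >= MIN_SEPARATION and guarded_ok
    else:
        star_span, separation = 0, -1
        crit_ii = crit_iii = False

    candidate.star_span_length = star_span
    candidate.separation = separation
    crit_dg = candidate.delta_g <= dg_threshold
    candidate.criteria = {"i": crit_i, "ii": crit_ii, "iii": crit_iii, "dG": crit_dg}
    candidate.verdict = crit_i and crit_ii and crit_iii and crit_dg
    return candidate


def repeat_filter(
    candidates: list[HairpinCandidate],
    repeat_features: list[tuple[str, int, int]],
) -> list[HairpinCandidate]:
    """Drop candidates whose window overlaps any repeat feature by >= 1 nt."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in repeat_features:
        by_chrom.setdefault(chrom, []).append((start, end))
    kept = []
    for cand in candidates:
        feats = by_chrom.get(cand.chrom, ())
        if any(cand.window_start < e and cand.window_end > s for s, e in feats):
            continue
        kept.append(cand)
    return kept


def classify_known_novel(
    key_sequence: str,
    mature_references: dict[str, str],
    max_mismatch: int = 2,
    max_length_diff: int = 2,
) -> tuple[str, str | None]:
    """Known iff some reference matches with <= max_mismatch substitutions
    over the full shorter length at some ungapped offset, with length
    difference <= max_length_diff. Returns (status, best reference id)."""
    if not mature_references:
        log.warning("empty mature reference set: all candidates called novel")
        return "novel", None
    best_id, best_mm = None, max_mismatch + 1
    for ref_id in sorted(mature_references):
        ref = mature_references[ref_id].upper().replace("U", "T")
        if abs(len(ref) - len(key_sequence)) > max_length_diff:
            continue
        short, long_ = sorted((key_sequence, ref), key=len)
        for off in range(len(long_) - len(short) + 1):
            mm = sum(a != b for a, b in zip(short, long_[off : off + len(short)]))
            if mm < best_mm:
                best_mm, best_id = mm, ref_id
    if best_id is not None and best_mm <= max_mismatch:
        return "known", best_id
    return "novel", best_id


def discover(
    genome: dict[str, str],
    genome_hits: dict[str, list[AlignmentHit]],
    tag_abundance: dict[str, int],
    mature_references: dict[str, str] | None = None,
    repeat_features: list[tuple[str, int, int]] | None = None,
    *,
    backend: str = "baseline",
    dg_threshold: float = DG_THRESHOLD,
    window_length: int = WINDOW_LENGTH,
    max_loci: int = MAX_LOCI,
    max_candidates: int | None = None,
    size_classes: tuple[int, ...] = (20, 21, 22),
) -> list[MirnaCall]:
    """Run the full discovery pipeline and return passing calls.

    `max_candidates` caps the number of folded candidates by decreasing tag
    abundance (desk-scale concession; unlimited when None). Final calls are
    restricted to `size_classes` lengths; pass None to keep all sizes.
    """
    cands = candidate_loci(genome_hits, max_loci=max_loci)
    if max_candidates is not None and len(cands) > max_candidates:
        cands.sort(key=lambda c: (-tag_abundance.get(c[0], 0), c[0]))
        cands = cands[:max_candidates]
    evaluated: list[HairpinCandidate] = []
    for seq, hit in cands:
        win = extract_window(genome, hit, length=window_length)
        if win is None:
            continue
        window, (chrom, start, end, strand) = win
        if seq not in window:
            continue  # placement straddles the shifted window edge
        structure, dg = _fold.fold(window, backend=backend)
        cand = HairpinCandidate(
            key_sequence=seq,
            window_sequence=window,
            chrom=chrom,
            window_start=start,
            window_end=end,
            strand=strand,
            structure=structure,
            delta_g=dg,
        )
        evaluate_hairpin(cand, dg_threshold=dg_threshold)
        if cand.verdict:
            evaluated.append(cand)
    if repeat_features:
        evaluated = repeat_filter(evaluated, repeat_features)
    calls: list[MirnaCall] = []
    for cand in evaluated:
        if size_classes is not None and len(cand.key_sequence) not in size_classes:
            continue
        status, ref_id = classify_known_novel(cand.key_sequence, mature_references or {})
        calls.append(
            MirnaCall(
                candidate=cand,
                status=status if mature_references else "novel",
                matched_reference_id=ref_id,
                size_class=len(cand.key_sequence),
            )
        )
    return calls
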