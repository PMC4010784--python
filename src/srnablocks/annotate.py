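"""Annotation of differentially expressed blocks: key sequences, size
histograms, similarity search against known matures, and the
miRNA-like / siRNA-gene / siRNA-TE classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mirna_discovery
from .aligner import AlignmentHit
from .blocks import Block
from .sequtils import mononucleotide_shuffle

SW_MATCH = 5
SW_MISMATCH = -4
SW_GAP = -10
SIMILARITY_ALPHA = 0.01
STRAND_BIAS_MIN = 0.9
OVERLAP_MIN = 0.5
MIRNA_SIZES = (20, 21, 22)
HISTOGRAM_SIZES = (20, 21, 22, 23, 24)


@dataclass
class BlockAnnotation:
    block_id: str
    key_sequence: str
    key_abundance: float
    size_histogram: dict[int, float]
    dominant_size: int | None
    strand_bias: float
    hairpin_verdict: bool
    best_mature_hit: str | None
    similarity_p: float | None
    overlap_class: str  # gene | TE | none
    final_class: str = "unclassified"
    extras: dict = field(default_factory=dict)


def key_sequence(block_tags: dict[str, float]) -> str:
    """Most abundant member tag; ties broken by smallest sequence."""
    assert block_tags, "empty block"
    return min(block_tags, key=lambda s: (-block_tags[s], s))


def block_size_distribution(block_tags: dict[str, float]) -> tuple[dict[int, float], int | None]:
    """Abundance fraction per length 20-24 nt of the block total.

    Lengths outside 20-24 count toward the total but not the histogram, so
    the fractions sum to <= 1. Returns (histogram, dominant length or None).
    """
    total = sum(block_tags.values())
    hist = {size: 0.0 for size in HISTOGRAM_SIZES}
    for seq, abund in block_tags.items():
        if len(seq) in hist:
            hist[len(seq)] += abund
    if total <= 0:
        return hist, None
    hist = {size: v / total for size, v in hist.items()}
    if all(v == 0 for v in hist.values()):
        return hist, None
    dominant = max(hist, key=lambda s: (hist[s], -s))
    return hist, dominant


def _sw_scores(queries: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Smith-Waterman local scores of many equal-length queries vs one
    reference, vectorised over the query axis (linear gap penalty)."""
    nq, lq = queries.shape
    lr = len(ref)
    best = np.zeros(nq, dtype=np.int64)
    prev = np.zeros((nq, lr + 1), dtype=np.int64)
    for i in range(1, lq + 1):
        cur = np.zeros((nq, lr + 1), dtype=np.int64)
        qi = queries[:, i - 1][:, None]
        sub = np.where(qi == ref[None, :], SW_MATCH, SW_MISMATCH)
        for j in range(1, lr + 1):
            diag = prev[:, j - 1] + sub[:, j - 1]
            up = prev[:, j] + SW_GAP
            left = cur[:, j - 1] + SW_GAP
            cur[:, j] = np.maximum(0, np.maximum(diag, np.maximum(up, left)))
        best = np.maximum(best, cur.max(axis=1))
        prev = cur
    return best


def smith_waterman_score(query: str, ref: str) -> int:
    """Best local alignment score (match +5, mismatch -4, gap -10)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)[None, :]
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    return int(_sw_scores(q, r)[0])


def mature_similarity_search(
    query: str,
    reference_set: dict[str, str],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[str | None, int, float]:
    """Best local-alignment hit plus a shuffle-based empirical p-value.

    p = (1 + #shuffled queries scoring >= observed) / (n_shuffles + 1);
    a hit is significant when p < 0.01. Deterministic given the seed.
    """
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    refs = {
        name: np.frombuffer(seq.upper().replace("U", "T").encode(), dtype=np.uint8)
        for name, seq in reference_set.items()
    }
    rng = np.random.default_rng(seed)
    shuffled = [mononucleotide_shuffle(query, rng) for _ in range(n_shuffles)]
    all_queries = np.array(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in [query, *shuffled]]
    )
    best_name, best_score = None, -1
    null_best = np.zeros(n_shuffles, dtype=np.int64)
    for name in sorted(refs):
        scores = _sw_scores(all_queries, refs[name])
        if scores[0] > best_score:
            best_score, best_name = int(scores[0]), name
        null_best = np.maximum(null_best, scores[1:])
    p = (1 + int((null_best >= best_score).sum())) / (n_shuffles + 1)
    return best_name, best_score, float(p)


def _overlap_fractions(
    members: list[AlignmentHit],
    abundances: dict[str, float],
    features: list[tuple[str, int, int, str]],
) -> dict[str, float]:
    """Fraction of block abundance whose placements overlap gene / TE."""
    gene_feats = [(c, s, e) for c, s, e, t in features if t == "gene"]
    te_feats = [(c, s, e) for c, s, e, t in features if t == "transposable_element"]
    total = 0.0
    in_gene = 0.0
    in_te = 0.0
    for h in members:
        a = abundances.get(h.tag_sequence, 0.0)
        total += a
        if any(c == h.chrom and h.start < e and h.end > s for c, s, e in gene_feats):
            in_gene += a
        if any(c == h.chrom and h.start < e and h.end > s for c, s, e in te_feats):
            in_te += a
    if total <= 0:
        return {"gene": 0.0, "TE": 0.0}
    return {"gene": in_gene / total, "TE": in_te / total}


def classify_block(
    dominant_size: int | None,
    strand_bias: float,
    hairpin_verdict: bool,
    overlap_fractions: dict[str, float],
    *,
    strand_bias_min: float = STRAND_BIAS_MIN,
    overlap_min: float = OVERLAP_MIN,
) -> str:
    """miRNA-like (20-22 nt dominant, one strand, hairpin) else TE-siRNA
    else genic siRNA else unclassified. TE takes precedence over gene."""
    if (
        dominant_size in MIRNA_SIZES
        and strand_bias >= strand_bias_min
        and hairpin_verdict
    ):
        return "mirna_like"
    if overlap_fractions.get("TE", 0.0) >= overlap_min:
        return "sirna_te"
    if overlap_fractions.get("gene", 0.0) >= overlap_min:
        return "sirna_gene"
    return "unclassified"


def annotate_block(
    block: Block,
    members: list[AlignmentHit],
    tag_totals: dict[str, float],
    genome: dict[str, str],
    features: list[tuple[str, int, int, str]],
    mature_references: dict[str, str] | None = None,
    *,
    fold_backend: str = "baseline",
    dg_threshold: float = mirna_discovery.DG_THRESHOLD,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> BlockAnnotation:
    """Full annotation of one block from its member placements.

    `tag_totals` maps member tag sequence to its summed abundance across
    libraries; `features` are (chrom, start, end, type) intervals.
    """
    assert members, "block has no member placements"
    block_tags = {
        seq: tag_totals.get(seq, 0.0)
        for seq in {h.tag_sequence for h in members}
    }
    key = key_sequence(block_tags)
    hist, dominant = block_size_distribution(block_tags)

    by_strand = {"+": 0.0, "-": 0.0}
    placements_in_block: dict[str, int] = {}
    for h in members:
        placements_in_block[h.tag_sequence] = placements_in_block.get(h.tag_sequence, 0) + 1
    for h in members:
        share = tag_totals.get(h.tag_sequence, 0.0) / placements_in_block[h.tag_sequence]
        by_strand[h.strand] += share
    total_strand = by_strand["+"] + by_strand["-"]
    strand_bias = (
        max(by_strand.values()) / total_strand if total_strand > 0 else 1.0
    )

    key_hits = [h for h in members if h.tag_sequence == key]
    hairpin_verdict = False
    for hit in key_hits[:1]:
        win = mirna_discovery.extract_window(genome, hit)
        if win is None:
            continue
        window, (chrom, start, end, strand) = win
        if key not in window:
            continue
        structure, dg = mirna_discovery._fold.fold(window, backend=fold_backend)
        cand = mirna_discovery.HairpinCandidate(
            key_sequence=key, window_sequence=window, chrom=chrom,
            window_start=start, window_end=end, strand=strand,
            structure=structure, delta_g=dg,
        )
        mirna_discovery.evaluate_hairpin(cand, dg_threshold=dg_threshold)
        hairpin_verdict = cand.verdict

    best_hit, sim_p = None, None
    if mature_references:
        best_hit, _score, sim_p = mature_similarity_search(
            key, mature_references, n_shuffles=n_shuffles, seed=seed
        )
        if sim_p >= SIMILARITY_ALPHA:
            best_hit = None

    fractions = _overlap_fractions(members, tag_totals, features)
    if fractions["TE"] >= OVERLAP_MIN:
        overlap_class = "TE"
    elif fractions["gene"] >= OVERLAP_MIN:
        overlap_class = "gene"
    else:
        overlap_class = "none"

    final = classify_block(dominant, strand_bias, hairpin_verdict, fractions)
    return BlockAnnotation(
        block_id=block.block_id,
        key_sequence=key,
        key_abundance=block_tags[key],
        size_histogram=hist,
        dominant_size=dominant,
        strand_bias=strand_bias,
        hairpin_verdict=hairpin_verdict,
        best_mature_hit=best_hit,
        similarity_p=sim_p,
        overlap_class=overlap_class,
        final_class=final,
        extras={"overlap_fractions": fractions},
    )


def annotations_to_frame(annotations: list[BlockAnnotation]) -> pd.DataFrame:
    if not annotations:
        return pd.DataFrame(
            columns=["key_sequence", "key_abundance", "dominant_size", "strand_bias",
                     "hairpin_verdict", "best_mature_hit", "similarity_p",
                     "overlap_class", "final_class"]
        ).rename_axis("block_id")
    rows = []
    for a in annotations:
        row = {
            "block_id": a.block_id,
            "key_sequence": a.key_sequence,
            "key_abundance": a.key_abundance,
            "dominant_size": a.dominant_size,
            "strand_bias": a.strand_bias,
            "hairpin_verdict": a.hairpin_verdict,
            "best_mature_hit": a.best_mature_hit,
            "similarity_p": a.similarity_p,
            "overlap_class": a.overlap_class,
            "final_class": a.final_class,
        }
        for size, frac in a.size_histogram.items():
            row[f"frac_{size}nt"] = frac
        rows.append(row)
    return pd.DataFrame(rows).set_index("block_id")
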