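"""Synthetic genome / annotation / small-RNA library generator with
machine-readable ground truth.

The simulator plants miRNA hairpin loci (validated against the hairpin
evaluator before the genome is emitted), double-stranded TE and genic
siRNA clusters, tRNA/rDNA decoy contigs and organellar contigs, assigns
heavy-tailed locus abundances, applies per-library fold-change plans and
emits exact-depth multinomial read sets with per-base substitution errors.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import mirna_discovery
from .aligner import AlignmentHit, ReferenceBundle
from .blocks import build_blocks
from .sequtils import random_seq, revcomp

NUCLEAR_CLASSES = ("mirna", "sirna_te", "sirna_gene")
DECOY_CLASSES = ("trna", "rdna", "plastid")

_PAIRABLE = {
    "A": "T",
    "T": "A",
    "C": "G",
    "G": "C",
}
# bases that can pair (WC or GU wobble) with the given base
_CAN_PAIR = {
    "A": {"T"},
    "C": {"G"},
    "G": {"C", "T"},
    "T": {"A", "G"},
}


@dataclass
class Library:
    library_id: str
    tissue: str
    light: str
    depth: int


def default_library_design(depth: int = 30_000) -> list[Library]:
    libs = []
    for tissue in ("cotyledon", "hook_concave", "hook_convex", "hypocotyl"):
        for light in ("dark", "fr"):
            libs.append(Library(f"{tissue}_{light}", tissue, light, depth))
    return libs


#: default planted differential loci for the eight-library design
DEFAULT_DE_PLAN = (
    ("mirna_0000", "hook_convex_fr_vs_hook_convex_dark", 6.0),
    ("mirna_0001", "cotyledon_fr_vs_cotyledon_dark", 4.0),
    ("te_0000", "hook_convex_dark_vs_hook_convex_fr", 4.0),
    ("te_0001", "hook_concave_dark_vs_hook_concave_fr", 4.0),
    ("gene_0000", "hypocotyl_fr_vs_hypocotyl_dark", 5.0),
)


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 120_000
    n_chromosomes: int = 2
    n_mirna_loci: int = 12
    n_te_loci: int = 6
    n_gene_sirna_loci: int = 5
    n_decoy_trna: int = 12
    n_decoy_rdna: int = 4
    n_plastid_contigs: int = 2
    n_repeat_features: int = 2
    library_design: list[Library] = dc_field(default_factory=default_library_design)
    # (locus_id, "libA_vs_libB", fold): locus abundance in libA is fold x libB
    de_plan: list[tuple[str, str, float]] = dc_field(
        default_factory=lambda: list(DEFAULT_DE_PLAN)
    )
    error_rate: float = 0.005
    abundance_lognormal_mu_sigma: tuple[float, float] = (4.0, 1.5)
    # base weight given to fold-plan loci; None = log-normal median
    de_base_weight: float | None = None
    decoy_fraction: float = 0.40
    plastid_fraction: float = 0.03
    gc: float = 0.5
    block_gap: int = 100
    min_spacing: int = 500
    te_length_range: tuple[int, int] = (1000, 3000)
    gene_length_range: tuple[int, int] = (500, 1500)

    def validate(self) -> None:
        if self.genome_length < 50_000:
            raise ValueError("genome_length must be >= 50,000")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        for lib in self.library_design:
            if lib.depth <= 0:
                raise ValueError(f"depth_reads must be > 0 ({lib.library_id})")
        for locus_id, comparison, fold in self.de_plan:
            if fold <= 0:
                raise ValueError(f"fold_change must be > 0 ({locus_id})")
            if "_vs_" not in comparison:
                raise ValueError(f"comparison must be 'libA_vs_libB' ({comparison})")


@dataclass
class TruthLocus:
    locus_id: str
    locus_class: str
    chrom: str
    start: int
    end: int
    strand: str
    mature: str | None
    base_weight: float = 0.0
    expected: dict[str, float] = dc_field(default_factory=dict)  # lib -> E[reads]
    folds: dict[str, float] = dc_field(default_factory=dict)  # lib -> multiplier


@dataclass
class TruthTable:
    loci: list[TruthLocus]

    def by_id(self) -> dict[str, TruthLocus]:
        return {l.locus_id: l for l in self.loci}

    def of_class(self, *classes: str) -> list[TruthLocus]:
        return [l for l in self.loci if l.locus_class in classes]


@dataclass
class Feature:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    ftype: str  # gene | transposable_element | repeat | miRNA_primary_transcript
    feature_id: str


def plant_hairpin(
    mature: str,
    pairing_fraction: float,
    loop_length: int,
    rng: np.random.Generator | None = None,
) -> str:
    """mature + loop + mutated reverse complement, a fold-by-design hairpin.

    The star arm differs from the exact reverse complement at
    floor((1 - pairing_fraction) * len(mature)) positions, each mutated to a
    base that cannot pair the corresponding mature base, so at least
    pairing_fraction of the mature bases can pair. The loop keeps mature and
    star separated by loop_length nt.
    """
    if not 20 <= len(mature) <= 22:
        raise ValueError("mature sequence must be 20-22 nt")
    if pairing_fraction <= 0.75:
        raise ValueError("pairing_fraction must exceed 0.75")
    if loop_length < 20:
        raise ValueError("loop_length must be at least 20 bases")
    rng = rng if rng is not None else np.random.default_rng(0)
    star = list(revcomp(mature))
    n_mut = math.floor((1.0 - pairing_fraction) * len(mature))
    if n_mut:
        positions = rng.choice(len(star), size=n_mut, replace=False)
        for pos in positions:
            mature_base = mature[len(mature) - 1 - pos]
            choices = [b for b in "ACGT" if b not in _CAN_PAIR[mature_base]]
            star[pos] = choices[rng.integers(len(choices))]
    loop = random_seq(rng, loop_length, gc=0.4)
    return mature + loop + "".join(star)


def _validate_hairpin_window(window: str, mature_oriented: str, dg_threshold: float) -> bool:
    structure, dg = mirna_discovery._fold.fold(window, backend="baseline")
    cand = mirna_discovery.HairpinCandidate(
        key_sequence=mature_oriented,
        window_sequence=window,
        chrom="_",
        window_start=0,
        window_end=len(window),
        strand="+",
        structure=structure,
        delta_g=dg,
    )
    if mature_oriented not in window:
        return False
    mirna_discovery.evaluate_hairpin(cand, dg_threshold=dg_threshold)
    return cand.verdict


def generate_genome(
    config: SimConfig,
) -> tuple[ReferenceBundle, list[Feature], TruthTable]:
    """Build references, annotation and truth for one simulation.

    Nuclear loci are laid out with at least `min_spacing` nt between them so
    that no two planted loci merge at the default block gap; every planted
    miRNA window must pass the hairpin evaluator under the baseline folder
    before the genome is accepted.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 17])

    n_nuclear = config.n_mirna_loci + config.n_te_loci + config.n_gene_sirna_loci
    per_chrom_len = config.genome_length // config.n_chromosomes
    # worst-case footprint check before doing any work
    worst = (
        config.n_mirna_loci * 120
        + config.n_te_loci * config.te_length_range[1]
        + config.n_gene_sirna_loci * config.gene_length_range[1]
        + (n_nuclear + config.n_repeat_features + 2 * config.n_chromosomes)
        * (config.min_spacing + 300)
    )
    if worst > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too small for "
            f"{n_nuclear} loci at spacing {config.min_spacing}"
        )

    plan: list[tuple[str, str]] = []  # (class, locus_id)
    plan += [("mirna", f"mirna_{i:04d}") for i in range(config.n_mirna_loci)]
    plan += [("sirna_te", f"te_{i:04d}") for i in range(config.n_te_loci)]
    plan += [("sirna_gene", f"gene_{i:04d}") for i in range(config.n_gene_sirna_loci)]
    plan += [("repeat", f"repeat_{i:04d}") for i in range(config.n_repeat_features)]
    order = rng.permutation(len(plan))

    chrom_names = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursors = {c: 0 for c in chrom_names}
    loci: list[TruthLocus] = []
    features: list[Feature] = []
    pending_hairpins: list[tuple[TruthLocus, int, int]] = []  # locus, mat_len, loop_len

    def emit_background(chrom: str, length: int) -> None:
        chrom_parts[chrom].append(random_seq(rng, length, gc=config.gc))
        cursors[chrom] += length

    next_chrom = 0
    for idx in order:
        cls, locus_id = plan[idx]
        chrom = chrom_names[next_chrom % len(chrom_names)]
        next_chrom += 1
        spacing = config.min_spacing + int(rng.integers(0, 200))
        emit_background(chrom, spacing)
        start = cursors[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "mirna":
            mat_len = int(rng.choice([20, 21, 22], p=[0.2, 0.6, 0.2]))
            loop_len = int(rng.integers(25, 41))
            mature = random_seq(rng, mat_len, gc=0.6)
            precursor = plant_hairpin(mature, 0.9, loop_len, rng)
            text = precursor if strand == "+" else revcomp(precursor)
            chrom_parts[chrom].append(text)
            cursors[chrom] += len(text)
            if strand == "+":
                m_start, m_end = start, start + mat_len
            else:
                m_start = start + len(text) - mat_len
                m_end = start + len(text)
            locus = TruthLocus(locus_id, "mirna", chrom, m_start, m_end, strand, mature)
            loci.append(locus)
            pending_hairpins.append((locus, mat_len, loop_len))
            features.append(
                Feature(chrom, start, cursors[chrom], strand,
                        "miRNA_primary_transcript", locus_id)
            )
        elif cls in ("sirna_te", "sirna_gene"):
            lo, hi = (
                config.te_length_range if cls == "sirna_te" else config.gene_length_range
            )
            length = int(rng.integers(lo, hi + 1))
            chrom_parts[chrom].append(random_seq(rng, length, gc=config.gc))
            cursors[chrom] += length
            loci.append(TruthLocus(locus_id, cls, chrom, start, start + length, strand, None))
            ftype = "transposable_element" if cls == "sirna_te" else "gene"
            features.append(Feature(chrom, start, start + length, strand, ftype, locus_id))
        else:  # standalone repeat feature, no reads emitted
            length = int(rng.integers(200, 401))
            chrom_parts[chrom].append(random_seq(rng, length, gc=config.gc))
            cursors[chrom] += length
            features.append(Feature(chrom, start, start + length, "+", "repeat", locus_id))

    for chrom in chrom_names:
        tail = per_chrom_len - cursors[chrom]
        emit_background(chrom, max(tail, config.min_spacing))

    genome = {c: "".join(chrom_parts[c]) for c in chrom_names}

    # re-fold every planted hairpin in its final genomic context; redraw the
    # locus (same lengths, so coordinates stay fixed) until it passes
    win_len = mirna_discovery.WINDOW_LENGTH
    for locus, mat_len, loop_len in pending_hairpins:
        for attempt in range(100):
            hit = AlignmentHit("", locus.chrom, locus.start, locus.end, locus.strand, 0)
            window, _coords = mirna_discovery.extract_window(genome, hit, win_len)
            if _validate_hairpin_window(window, locus.mature, mirna_discovery.DG_THRESHOLD):
                break
            mature = random_seq(rng, mat_len, gc=0.6)
            precursor = plant_hairpin(mature, 0.9, loop_len, rng)
            if locus.strand == "+":
                pre_start = locus.start
                text = precursor
            else:
                pre_start = locus.end - len(precursor)
                text = revcomp(precursor)
            seq = genome[locus.chrom]
            genome[locus.chrom] = (
                seq[:pre_start] + text + seq[pre_start + len(text):]
            )
            locus.mature = mature
        else:
            raise RuntimeError(f"could not plant a passing hairpin for {locus.locus_id}")

    # decoy and organellar contigs
    trna, rdna, chloroplast, mitochondrion = {}, {}, {}, {}
    for i in range(config.n_decoy_trna):
        name = f"trna_{i:03d}"
        trna[name] = random_seq(rng, int(rng.integers(70, 91)), gc=0.55)
        loci.append(TruthLocus(f"decoy_{name}", "trna", name, 0, len(trna[name]), "+", None))
    for i in range(config.n_decoy_rdna):
        name = f"rdna_{i:03d}"
        rdna[name] = random_seq(rng, int(rng.integers(1500, 2501)), gc=0.55)
        loci.append(TruthLocus(f"decoy_{name}", "rdna", name, 0, len(rdna[name]), "+", None))
    for i in range(config.n_plastid_contigs):
        name = f"chloroplast_{i:02d}"
        chloroplast[name] = random_seq(rng, 4000, gc=config.gc)
        loci.append(TruthLocus(f"decoy_{name}", "plastid", name, 0, 4000, "+", None))
    name = "mitochondrion_01"
    mitochondrion[name] = random_seq(rng, 4000, gc=config.gc)
    loci.append(TruthLocus(f"decoy_{name}", "plastid", name, 0, 4000, "+", None))

    truth = TruthTable(loci=loci)
    _assign_abundances(truth, config, rng)

    # spacing invariant: planted nuclear loci never merge at the default gap
    pseudo = [
        AlignmentHit("", l.chrom, l.start, l.end, "+", 0)
        for l in truth.of_class(*NUCLEAR_CLASSES)
    ]
    if pseudo:
        merged = build_blocks(pseudo, gap=config.block_gap)
        assert len(merged) == len(pseudo), "planted loci merge at the default block gap"

    refs = ReferenceBundle(
        trna=trna, rdna=rdna, genome=genome,
        chloroplast=chloroplast, mitochondrion=mitochondrion,
    )
    return refs, features, truth


def _assign_abundances(truth: TruthTable, config: SimConfig, rng: np.random.Generator) -> None:
    """Log-normal base weights, group shares, fold plan, expected counts.

    Loci named in the fold plan get the log-normal median as base weight:
    within a fixed-depth library the fold multiplier is paid for by all
    other loci, so keeping planted-DE loci off the heavy tail keeps that
    composition coupling well below the fold-change cutoff.
    """
    mu, sigma = config.abundance_lognormal_mu_sigma
    for locus in truth.loci:
        locus.base_weight = float(rng.lognormal(mu, sigma))
    by_id = truth.by_id()
    for locus_id, comparison, fold in config.de_plan:
        if locus_id not in by_id:
            raise ValueError(f"de_plan references unknown locus {locus_id}")
        lib_a = comparison.split("_vs_")[0]
        by_id[locus_id].folds[lib_a] = by_id[locus_id].folds.get(lib_a, 1.0) * fold
        by_id[locus_id].base_weight = (
            float(np.exp(mu)) if config.de_base_weight is None else config.de_base_weight
        )

    nuclear = truth.of_class(*NUCLEAR_CLASSES)
    decoys = truth.of_class("trna", "rdna")
    plastid = truth.of_class("plastid")
    shares = {
        "nuclear": 1.0 - config.decoy_fraction - config.plastid_fraction,
        "decoy": config.decoy_fraction,
        "plastid": config.plastid_fraction,
    }
    for lib in config.library_design:
        for group, members in (
            ("nuclear", nuclear), ("decoy", decoys), ("plastid", plastid)
        ):
            if not members:
                continue
            weights = np.array(
                [l.base_weight * l.folds.get(lib.library_id, 1.0) for l in members]
            )
            probs = weights / weights.sum() * shares[group]
            for locus, p in zip(members, probs):
                locus.expected[lib.library_id] = float(p * lib.depth)
    # renormalise expectations so each library sums exactly to its depth
    for lib in config.library_design:
        total = sum(l.expected.get(lib.library_id, 0.0) for l in truth.loci)
        for locus in truth.loci:
            if lib.library_id in locus.expected:
                locus.expected[lib.library_id] *= lib.depth / total


def _emit_locus_reads(
    locus: TruthLocus,
    n: int,
    refs: ReferenceBundle,
    rng: np.random.Generator,
) -> list[str]:
    if n == 0:
        return []
    if locus.locus_class == "mirna":
        chrom = refs.genome[locus.chrom]
        s, e = locus.start, locus.end
        if locus.strand == "+":
            exact = chrom[s:e]
            minus1 = chrom[s : e - 1]
            plus1 = chrom[s : e + 1]
        else:
            exact = revcomp(chrom[s:e])
            minus1 = revcomp(chrom[s + 1 : e])
            plus1 = revcomp(chrom[max(s - 1, 0) : e])
        variants = [exact, minus1, plus1]
        picks = rng.choice(3, size=n, p=[0.8, 0.1, 0.1])
        return [variants[v] for v in picks]
    if locus.locus_class in ("sirna_te", "sirna_gene"):
        chrom = refs.genome[locus.chrom]
        lengths = rng.choice([23, 24], size=n)
        strands = rng.random(n) < 0.5
        out = []
        for length, minus in zip(lengths, strands):
            start = int(rng.integers(locus.start, locus.end - int(length) + 1))
            frag = chrom[start : start + int(length)]
            out.append(revcomp(frag) if minus else frag)
        return out
    # decoy / organellar fragments
    source = {
        "trna": refs.trna,
        "rdna": refs.rdna,
        "plastid": (
            refs.chloroplast if locus.chrom in refs.chloroplast else refs.mitochondrion
        ),
    }[locus.locus_class]
    contig = source[locus.chrom]
    lengths = rng.integers(18, 29, size=n)
    out = []
    for length in lengths:
        length = min(int(length), len(contig))
        start = int(rng.integers(0, len(contig) - length + 1))
        out.append(contig[start : start + length])
    return out


def _apply_errors(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate <= 0:
        return reads
    out = []
    for read in reads:
        k = rng.binomial(len(read), error_rate)
        if k == 0:
            out.append(read)
            continue
        chars = list(read)
        for pos in rng.choice(len(read), size=k, replace=False):
            alternatives = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = alternatives[rng.integers(3)]
        out.append("".join(chars))
    return out


def library_rng(config: SimConfig, lib_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1000 + lib_index])


def sample_locus_counts(
    truth: TruthTable, lib: Library, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial per-locus read counts for one library (sums to depth)."""
    expected = np.array([l.expected.get(lib.library_id, 0.0) for l in truth.loci])
    if expected.sum() <= 0:
        raise ValueError(f"no expected abundance for library {lib.library_id}")
    return rng.multinomial(lib.depth, expected / expected.sum())


def simulate_libraries(
    truth: TruthTable,
    refs: ReferenceBundle,
    config: SimConfig,
) -> dict[str, list[str]]:
    """Exact-depth multinomial read sets per library.

    Reads are drawn from the per-library expected locus proportions stored
    in the truth table; the emitted read count equals depth_reads exactly.
    """
    if not truth.loci:
        raise ValueError("empty truth table")
    config.validate()
    libraries: dict[str, list[str]] = {}
    for lib_index, lib in enumerate(config.library_design):
        rng = library_rng(config, lib_index)
        counts = sample_locus_counts(truth, lib, rng)
        reads: list[str] = []
        for locus, n in zip(truth.loci, counts):
            reads.extend(_emit_locus_reads(locus, int(n), refs, rng))
        reads = _apply_errors(reads, config.error_rate, rng)
        assert len(reads) == lib.depth
        libraries[lib.library_id] = reads
    return libraries


def simulate_block_counts(
    n_null: int,
    n_de: int,
    fold: float,
    depth: int,
    seed: int,
    *,
    de_rpm: float = 100.0,
    mu_sigma: tuple[float, float] = (4.0, 1.5),
) -> tuple["pd.DataFrame", list[str]]:
    """Count-level two-library experiment for DE power / error studies.

    Null blocks share log-normal proportions across the two libraries
    ("lib_a", "lib_b"); planted blocks sit at `de_rpm` reads-per-million in
    lib_b and fold x that in lib_a. Returns (count matrix, planted ids).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    null_w = rng.lognormal(*mu_sigma, size=n_null)
    de_share = de_rpm / 1e6
    null_share = 1.0 - n_de * de_share
    p_b = np.concatenate([null_w / null_w.sum() * null_share,
                          np.full(n_de, de_share)])
    w_a = np.concatenate([null_w / null_w.sum() * null_share,
                          np.full(n_de, de_share * fold)])
    p_a = w_a / w_a.sum()
    ids = [f"null_{i:04d}" for i in range(n_null)] + [
        f"de_{i:04d}" for i in range(n_de)
    ]
    matrix = pd.DataFrame(
        {
            "lib_a": rng.multinomial(depth, p_a),
            "lib_b": rng.multinomial(depth, p_b),
        },
        index=ids, dtype=float,
    )
    matrix.index.name = "block_id"
    return matrix, ids[n_null:]
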