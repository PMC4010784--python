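"""End-to-end orchestration: simulate -> preprocess -> align -> blocks ->
differential expression -> miRNA discovery -> block annotation.

Every stage writes its outputs under the run directory and contributes a
section to `manifest.json`; re-running with the same config and seed
reproduces all outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, annotate, blocks, diffexp, io, mirna_discovery, preprocess, synthgen
from .synthgen import SimConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunables, defaulting to the published parameterization where one
    exists (17-35 nt, <=3 mismatches on tRNA/rDNA, 20 RPM, 2-fold, alpha
    0.05, <=20 loci, 170 nt windows, -40 kcal/mol, 25 C)."""

    min_len: int = 17
    max_len: int = 35
    error_correct_mm: int = 1
    trna_rdna_mm: int = 3
    relaxed_mm: int = 3
    gap: int = 100
    rpm_min: float = 20.0
    fc_min: float = 2.0
    alpha: float = 0.05
    max_loci: int = 20
    window_length: int = 170
    dg_threshold: float = -40.0
    temperature: float = 25.0
    fold_backend: str = "baseline"
    max_candidates: int = 4000
    n_shuffles: int = 1000


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self):
        self.sim.seed = self.seed


def config_from_dict(data: dict) -> PipelineConfig:
    seed = int(data.get("seed", 0))
    sim_data = dict(data.get("sim", {}))
    lib_design = sim_data.pop("library_design", None)
    de_plan = sim_data.pop("de_plan", None)
    sim = SimConfig(**sim_data)
    if lib_design is not None:
        sim.library_design = [synthgen.Library(*row) for row in lib_design]
    if de_plan is not None:
        sim.de_plan = [(str(a), str(b), float(c)) for a, b, c in de_plan]
    params = PipelineParams(**data.get("params", {}))
    return PipelineConfig(seed=seed, sim=sim, params=params)


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": asdict(p),
        "stages": [],
    }

    # 1. simulate
    refs, features, truth = synthgen.generate_genome(config.sim)
    libraries = synthgen.simulate_libraries(truth, refs, config.sim)
    io.write_fasta(refs.genome, out / "genome.fa")
    io.write_fasta(refs.trna, out / "trna.fa")
    io.write_fasta(refs.rdna, out / "rdna.fa")
    io.write_fasta(refs.chloroplast, out / "chloroplast.fa")
    io.write_fasta(refs.mitochondrion, out / "mitochondrion.fa")
    io.write_gff3(features, out / "annotation.gff3")
    io.write_truth(truth, out / "truth.tsv")
    matures = {
        l.locus_id: l.mature for l in truth.of_class("mirna") if l.mature
    }
    io.write_fasta(matures, out / "mature.fa")
    for lib_id, reads in libraries.items():
        io.write_fastq(reads, out / f"reads_{lib_id}.fastq", prefix=lib_id)
    manifest["stages"].append(
        {"name": "simulate", "libraries": len(libraries),
         "loci": len(truth.loci), "reads": sum(len(r) for r in libraries.values())}
    )

    # 2. preprocess
    tags = {
        lib_id: preprocess.preprocess_library(
            reads, p.min_len, p.max_len, p.error_correct_mm
        )
        for lib_id, reads in libraries.items()
    }
    io.write_tags(tags, out / "tags.tsv")
    manifest["stages"].append(
        {"name": "preprocess",
         "unique_tags": sum(len(t) for t in tags.values()),
         "abundance": sum(sum(t.values()) for t in tags.values())}
    )

    # 3. hierarchical alignment
    from .aligner import hierarchical_filter

    triage = hierarchical_filter(
        tags, refs, relaxed_mm=p.relaxed_mm, trna_rdna_mm=p.trna_rdna_mm
    )
    triage.summary.to_csv(out / "triage.tsv", sep="\t", index=False)
    io.write_hits(triage.genome_hits, out / "genome_hits.tsv")
    genome_tags = set(triage.genome_hits)
    genome_tag_abund = {
        lib: {s: c for s, c in t.items() if s in genome_tags} for lib, t in tags.items()
    }
    manifest["stages"].append(
        {"name": "align",
         "categories": {
             cat: int(triage.summary.loc[triage.summary.category == cat, "reads"].sum())
             for cat in triage.summary.category.unique()
         }}
    )

    # 4. blocks and counts
    all_hits = [h for hits in triage.genome_hits.values() for h in hits]
    block_set = blocks.build_blocks(all_hits, gap=p.gap)
    matrix = blocks.weighted_counts(block_set, triage.genome_hits, genome_tag_abund)
    io.write_blocks_bed(block_set, out / "blocks.bed")
    matrix.to_csv(out / "block_counts.tsv", sep="\t")
    profiles = blocks.size_profiles(genome_tag_abund)
    profiles.to_csv(out / "size_profile.tsv", sep="\t")
    manifest["stages"].append({"name": "blocks", "blocks": len(block_set)})

    # 5. differential expression (six-contrast preset when applicable)
    libs = set(matrix.columns)
    comparisons = [
        c for c in diffexp.PAPER_COMPARISONS if {c[1], c[2]} <= libs
    ]
    if not comparisons and len(matrix.columns) >= 2:
        cols = sorted(matrix.columns)
        comparisons = [(f"{cols[1]}_vs_{cols[0]}", cols[1], cols[0])]
    de_tables = diffexp.run_all_comparisons(
        matrix, comparisons, rpm_min=p.rpm_min, fc_min=p.fc_min, alpha=p.alpha
    )
    de_counts = {}
    de_block_ids: set[str] = set()
    for label, table in de_tables.items():
        table.to_csv(out / f"de_{label}.tsv", sep="\t")
        sig = table.status.isin(["de_up", "de_down"])
        de_counts[label] = int(sig.sum())
        de_block_ids |= set(table.index[sig])
    manifest["stages"].append({"name": "de", "de_blocks": de_counts})

    # 6. miRNA discovery
    total_abund = {
        seq: sum(t.get(seq, 0) for t in genome_tag_abund.values())
        for seq in genome_tags
    }
    repeat_feats = [
        (f.chrom, f.start, f.end)
        for f in features
        if f.ftype in ("repeat", "transposable_element")
    ]
    calls = mirna_discovery.discover(
        refs.genome, triage.genome_hits, total_abund,
        mature_references=matures, repeat_features=repeat_feats,
        backend=p.fold_backend, dg_threshold=p.dg_threshold,
        window_length=p.window_length, max_loci=p.max_loci,
        max_candidates=p.max_candidates,
    )
    call_rows = [
        {"key_sequence": c.candidate.key_sequence, "chrom": c.candidate.chrom,
         "window_start": c.candidate.window_start, "window_end": c.candidate.window_end,
         "strand": c.candidate.strand, "delta_g": c.candidate.delta_g,
         "status": c.status, "matched_reference_id": c.matched_reference_id,
         "size_class": c.size_class}
        for c in calls
    ]
    pd.DataFrame(
        call_rows,
        columns=["key_sequence", "chrom", "window_start", "window_end", "strand",
                 "delta_g", "status", "matched_reference_id", "size_class"],
    ).to_csv(out / "mirna_calls.tsv", sep="\t", index=False)
    with open(out / "mirna_structures.txt", "w") as fh:
        for c in calls:
            fh.write(f">{c.candidate.chrom}:{c.candidate.window_start}"
                     f"-{c.candidate.window_end}({c.candidate.strand})\n")
            fh.write(c.candidate.window_sequence + "\n")
            fh.write(c.candidate.structure + "\n")
    manifest["stages"].append(
        {"name": "mirna",
         "calls": len(calls),
         "known": sum(1 for c in calls if c.status == "known")}
    )

    # 7. annotation of DE blocks + truth agreement
    members = blocks.block_members(block_set, triage.genome_hits)
    feat_tuples = [(f.chrom, f.start, f.end, f.ftype) for f in features]
    block_by_id = {b.block_id: b for b in block_set}

    def _annotate(bid: str) -> annotate.BlockAnnotation | None:
        mem = members.get(bid, [])
        if not mem:
            return None
        return annotate.annotate_block(
            block_by_id[bid], mem, total_abund, refs.genome, feat_tuples,
            mature_references=matures, fold_backend=p.fold_backend,
            dg_threshold=p.dg_threshold, n_shuffles=p.n_shuffles, seed=config.seed,
        )

    de_annotations = [a for a in (_annotate(b) for b in sorted(de_block_ids)) if a]
    annotate.annotations_to_frame(de_annotations).to_csv(
        out / "de_block_annotations.tsv", sep="\t"
    )

    agreement = classification_agreement(
        truth, block_set, _annotate
    )
    manifest["stages"].append(
        {"name": "annotate", "de_blocks_annotated": len(de_annotations),
         "classification_agreement": agreement}
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def classification_agreement(
    truth: synthgen.TruthTable,
    block_set: list[blocks.Block],
    annotate_fn,
) -> dict:
    """Agreement of block classification with planted mirna / sirna_te loci.

    A truth locus is scored when some block overlaps it; agreement is the
    fraction of scored loci whose overlapping block is classified as the
    planted class."""
    want = {"mirna": "mirna_like", "sirna_te": "sirna_te"}
    per_class: dict[str, dict[str, int]] = {
        cls: {"scored": 0, "correct": 0} for cls in want
    }
    cache: dict[str, annotate.BlockAnnotation | None] = {}
    for locus in truth.of_class(*want):
        hit_block = None
        for b in block_set:
            if b.chrom == locus.chrom and b.start < locus.end and b.end > locus.start:
                hit_block = b
                break
        if hit_block is None:
            continue
        if hit_block.block_id not in cache:
            cache[hit_block.block_id] = annotate_fn(hit_block.block_id)
        ann = cache[hit_block.block_id]
        if ann is None:
            continue
        per_class[locus.locus_class]["scored"] += 1
        if ann.final_class == want[locus.locus_class]:
            per_class[locus.locus_class]["correct"] += 1
    out = {}
    for cls, d in per_class.items():
        out[cls] = {
            **d,
            "agreement": d["correct"] / d["scored"] if d["scored"] else None,
        }
    return out
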