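import numpy as np
import pytest
from conftest import tiny_config

from srnablocks import mirna_discovery, synthgen
from srnablocks.aligner import AlignmentHit
from srnablocks.fold import fold_baseline
from srnablocks.sequtils import hamming, revcomp
from srnablocks.synthgen import (
    Library,
    SimConfig,
    plant_hairpin,
    sample_locus_counts,
    library_rng,
)


class TestSimConfigValidation:
    def test_genome_too_small(self):
        with pytest.raises(ValueError, match="genome_length"):
            tiny_config(genome_length=40_000).validate()

    def test_bad_error_rate(self):
        with pytest.raises(ValueError, match="error_rate"):
            tiny_config(error_rate=0.2).validate()

    def test_bad_depth(self):
        cfg = tiny_config()
        cfg.library_design[0].depth = 0
        with pytest.raises(ValueError, match="depth"):
            cfg.validate()

    def test_bad_fold(self):
        with pytest.raises(ValueError, match="fold"):
            tiny_config(de_plan=[("te_0000", "lib_a_vs_lib_b", -1.0)]).validate()


class TestPlantHairpin:
    def test_perfect_pairing(self, rng):
        mature = "ACGUACGUACGUACGUACGUA".replace("U", "T")
        precursor = plant_hairpin(mature, 1.0, 30, rng)
        assert len(precursor) == 21 + 30 + 21
        assert precursor[-21:] == revcomp(mature)

    def test_loop_too_short(self, rng):
        with pytest.raises(ValueError, match="at least 20"):
            plant_hairpin("A" * 21, 0.9, 19, rng)

    def test_pairing_fraction_too_low(self, rng):
        with pytest.raises(ValueError, match="0.75"):
            plant_hairpin("A" * 21, 0.75, 30, rng)

    def test_mutation_budget(self, rng):
        # floor((1 - 0.8) * 21) = 4 positions may differ from the exact rc
        mature = "GCGTACGTAGCTAGCTAGCTA"
        for _ in range(10):
            precursor = plant_hairpin(mature, 0.8, 25, rng)
            star = precursor[-21:]
            assert hamming(star, revcomp(mature)) <= 4


class TestGenerateGenome:
    def test_empty_plan_only_decoys(self):
        cfg = tiny_config(
            n_mirna_loci=0, n_te_loci=0, n_gene_sirna_loci=0,
            n_repeat_features=0, de_plan=[],
        )
        _refs, _features, truth = synthgen.generate_genome(cfg)
        assert all(l.locus_class in ("trna", "rdna", "plastid") for l in truth.loci)

    def test_determinism(self):
        out = []
        for _ in range(2):
            refs, features, truth = synthgen.generate_genome(tiny_config(seed=3))
            libs = synthgen.simulate_libraries(truth, refs, tiny_config(seed=3))
            out.append((refs.genome, [tuple(vars(f).values()) for f in features],
                        [(l.locus_id, l.start, l.mature) for l in truth.loci], libs))
        assert out[0] == out[1]

    def test_sizing_error(self):
        cfg = tiny_config(genome_length=50_000, n_te_loci=30)
        with pytest.raises(ValueError, match="too small"):
            synthgen.generate_genome(cfg)

    def test_all_planted_hairpins_pass_evaluator(self):
        cfg = tiny_config(seed=21, n_mirna_loci=8)
        refs, _features, truth = synthgen.generate_genome(cfg)
        for locus in truth.of_class("mirna"):
            hit = AlignmentHit("", locus.chrom, locus.start, locus.end, locus.strand, 0)
            window, _ = mirna_discovery.extract_window(refs.genome, hit)
            assert locus.mature in window
            structure, dg = fold_baseline(window)
            cand = mirna_discovery.HairpinCandidate(
                key_sequence=locus.mature, window_sequence=window,
                chrom=locus.chrom, window_start=0, window_end=len(window),
                strand=locus.strand, structure=structure, delta_g=dg,
            )
            mirna_discovery.evaluate_hairpin(cand)
            assert cand.verdict, (locus.locus_id, cand.criteria)

    def test_loci_within_bounds_and_spaced(self, sim):
        cfg, refs, _features, truth = sim
        nuclear = truth.of_class("mirna", "sirna_te", "sirna_gene")
        for locus in nuclear:
            assert 0 <= locus.start < locus.end <= len(refs.genome[locus.chrom])
        by_chrom = {}
        for locus in nuclear:
            by_chrom.setdefault(locus.chrom, []).append((locus.start, locus.end))
        for ivals in by_chrom.values():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert s2 - e1 > cfg.block_gap

    def test_mirna_mature_length(self, sim):
        truth = sim[3]
        for locus in truth.of_class("mirna"):
            assert 20 <= len(locus.mature) <= 22

    def test_annotation_marks_all_types(self, sim):
        features = sim[2]
        types = {f.ftype for f in features}
        assert {"gene", "transposable_element", "repeat",
                "miRNA_primary_transcript"} <= types


class TestSimulateLibraries:
    def test_exact_depth(self, sim, libraries):
        cfg = sim[0]
        for lib in cfg.library_design:
            assert len(libraries[lib.library_id]) == lib.depth

    def test_empty_truth_rejected(self, sim):
        cfg, refs, _f, _t = sim
        with pytest.raises(ValueError, match="empty"):
            synthgen.simulate_libraries(synthgen.TruthTable(loci=[]), refs, cfg)

    def test_zero_error_mirna_reads_are_precursor_substrings(self):
        cfg = tiny_config(
            seed=9, n_mirna_loci=1, n_te_loci=0, n_gene_sirna_loci=0,
            n_repeat_features=0, de_plan=[], error_rate=0.0,
            decoy_fraction=0.0, plastid_fraction=0.0,
        )
        refs, _features, truth = synthgen.generate_genome(cfg)
        locus = truth.of_class("mirna")[0]
        chrom = refs.genome[locus.chrom]
        arm = chrom[max(0, locus.start - 2) : locus.end + 2]
        arm_oriented = arm if locus.strand == "+" else revcomp(arm)
        libs = synthgen.simulate_libraries(truth, refs, cfg)
        for reads in libs.values():
            assert reads  # everything comes from the single miRNA locus
            for read in reads:
                assert read in arm_oriented

    def test_planted_fold_ratio_expectation(self):
        # mean sampled-count ratio over 100 seeded replicates ~ planted fold
        cfg = tiny_config(
            seed=30, depth=100_000,
            de_plan=[("gene_0000", "lib_a_vs_lib_b", 4.0)],
            de_base_weight=5.0,
        )
        _refs, _features, truth = synthgen.generate_genome(cfg)
        locus = truth.by_id()["gene_0000"]
        idx = [l.locus_id for l in truth.loci].index("gene_0000")
        # composition coupling (fixed depth) keeps the model expectation
        # slightly below the planted fold; it must stay within a few percent
        model_ratio = locus.expected["lib_a"] / locus.expected["lib_b"]
        assert abs(model_ratio - 4.0) < 0.2
        ratios = []
        for rep in range(100):
            ca = sample_locus_counts(
                truth, cfg.library_design[0], np.random.default_rng([rep, 0])
            )[idx]
            cb = sample_locus_counts(
                truth, cfg.library_design[1], np.random.default_rng([rep, 1])
            )[idx]
            assert cb > 0
            ratios.append(ca / cb)
        mean = np.mean(ratios)
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - model_ratio) <= 3 * sem
        assert abs(mean - 4.0) <= 3 * sem + abs(model_ratio - 4.0)

    def test_sirna_reads_cover_both_strands(self, sim, libraries, tags, triage):
        _cfg, refs, _features, truth = sim
        te = truth.of_class("sirna_te")[0]
        strands = set()
        for tag, hits in triage.genome_hits.items():
            for h in hits:
                if h.chrom == te.chrom and h.start >= te.start and h.end <= te.end:
                    strands.add(h.strand)
        assert strands == {"+", "-"}
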