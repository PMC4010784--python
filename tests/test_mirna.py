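import numpy as np
import pytest

from srnablocks.aligner import AlignmentHit
from srnablocks.mirna_discovery import (
    HairpinCandidate,
    candidate_loci,
    classify_known_novel,
    discover,
    evaluate_hairpin,
    extract_window,
    repeat_filter,
)
from srnablocks.sequtils import random_seq, revcomp


def _hits(tag, n):
    return [AlignmentHit(tag, "c", 100 * i, 100 * i + len(tag), "+", 0) for i in range(n)]


class TestCandidateLoci:
    def test_over_20_loci_excluded(self):
        tag = "A" * 21
        assert candidate_loci({tag: _hits(tag, 21)}) == []

    def test_exactly_20_loci_included(self):
        tag = "A" * 21
        assert len(candidate_loci({tag: _hits(tag, 20)})) == 20

    def test_single_locus(self):
        tag = "A" * 21
        assert len(candidate_loci({tag: _hits(tag, 1)})) == 1


class TestExtractWindow:
    def test_centered(self):
        genome = {"c": "A" * 10_000}
        hit = AlignmentHit("T" * 21, "c", 500, 521, "+", 0)
        window, (chrom, start, end, strand) = extract_window(genome, hit)
        assert (start, end) == (425, 595)
        assert len(window) == 170

    def test_shifted_at_edge(self):
        genome = {"c": "A" * 10_000}
        hit = AlignmentHit("T" * 21, "c", 10, 31, "+", 0)
        _window, (_c, start, end, _s) = extract_window(genome, hit)
        assert (start, end) == (0, 170)

    def test_minus_strand_reverse_complements(self, rng):
        seq = random_seq(rng, 400)
        genome = {"c": seq}
        hit = AlignmentHit("x", "c", 200, 221, "-", 0)
        window, (_c, start, end, _s) = extract_window(genome, hit)
        assert window == revcomp(seq[start:end])

    def test_short_chromosome_rejected(self):
        genome = {"c": "A" * 100}
        hit = AlignmentHit("x", "c", 10, 31, "+", 0)
        assert extract_window(genome, hit) is None


def make_candidate(key, window, structure, delta_g):
    return HairpinCandidate(
        key_sequence=key, window_sequence=window, chrom="c",
        window_start=0, window_end=len(window), strand="+",
        structure=structure, delta_g=delta_g,
    )


def build_structure(length, pairs):
    chars = ["."] * length
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


KEY = "G" * 21
KEY_START = 40  # first occurrence of the key in the fixture windows
WINDOW = "A" * KEY_START + KEY + "A" * (170 - KEY_START - 21)


def hairpin_pairs(n_paired, star_lo, spread=1):
    """Nested pairs: key position KEY_START+i with a descending star arm."""
    return [
        (KEY_START + i, star_lo + (n_paired - 1 - i) * spread)
        for i in range(n_paired)
    ]


class TestEvaluateHairpin:
    def test_all_criteria_pass(self):
        cand = make_candidate(
            KEY, WINDOW, build_structure(170, hairpin_pairs(21, 100)), -50.0
        )
        evaluate_hairpin(cand)
        assert cand.criteria == {"i": True, "ii": True, "iii": True, "dG": True}
        assert cand.verdict

    def test_fail_only_i_with_15_of_21(self):
        # 15/21 = 71.4% <= 75%: criterion (i) fails, everything else holds
        pairs = hairpin_pairs(21, 100)[:15]
        cand = make_candidate(KEY, WINDOW, build_structure(170, pairs), -50.0)
        evaluate_hairpin(cand)
        assert cand.criteria == {"i": False, "ii": True, "iii": True, "dG": True}

    def test_16_of_21_passes_i(self):
        pairs = hairpin_pairs(21, 100)[:16]
        cand = make_candidate(KEY, WINDOW, build_structure(170, pairs), -50.0)
        evaluate_hairpin(cand)
        assert cand.criteria["i"] is True
        assert cand.paired_fraction == pytest.approx(16 / 21)

    def test_fail_only_ii_star_too_long(self):
        # star span 41 nt > 1.5 * 21 = 31.5
        pairs = hairpin_pairs(21, 100, spread=2)
        cand = make_candidate(KEY, WINDOW, build_structure(170, pairs), -50.0)
        evaluate_hairpin(cand)
        assert cand.criteria == {"i": True, "ii": False, "iii": True, "dG": True}

    def test_fail_only_iii_separation_19(self):
        # star arm starting 19 nt after the key end violates criterion (iii)
        pairs = hairpin_pairs(21, 80)
        cand = make_candidate(KEY, WINDOW, build_structure(170, pairs), -50.0)
        evaluate_hairpin(cand)
        assert cand.separation == 19
        assert cand.criteria == {"i": True, "ii": True, "iii": False, "dG": True}

    def test_fail_only_dg(self):
        cand = make_candidate(
            KEY, WINDOW, build_structure(170, hairpin_pairs(21, 100)), -39.0
        )
        evaluate_hairpin(cand)
        assert cand.criteria == {"i": True, "ii": True, "iii": True, "dG": False}

    def test_unpaired_key_fails_everything_but_dg(self):
        cand = make_candidate(KEY, WINDOW, "." * 170, -50.0)
        evaluate_hairpin(cand)
        assert cand.paired_fraction == 0.0
        assert not cand.verdict

    def test_key_not_in_window_asserts(self):
        cand = make_candidate("T" * 21, WINDOW, "." * 170, -50.0)
        with pytest.raises(AssertionError):
            evaluate_hairpin(cand)


class TestRepeatFilter:
    def _cand(self, start=100, end=270):
        cand = make_candidate(KEY, WINDOW, "." * 170, 0.0)
        cand.window_start, cand.window_end = start, end
        return cand

    def test_full_overlap_removed(self):
        assert repeat_filter([self._cand()], [("c", 0, 1000)]) == []

    def test_no_overlap_kept(self):
        assert len(repeat_filter([self._cand()], [("c", 500, 600)])) == 1

    def test_single_base_overlap_removed(self):
        assert repeat_filter([self._cand()], [("c", 269, 300)]) == []
        assert len(repeat_filter([self._cand()], [("c", 270, 300)])) == 1


class TestClassifyKnownNovel:
    REFS = {"mir1": "ACGTACGTACGTACGTACGTA"}

    def test_identical_is_known(self):
        status, ref = classify_known_novel("ACGTACGTACGTACGTACGTA", self.REFS)
        assert (status, ref) == ("known", "mir1")

    def test_three_mismatches_is_novel(self):
        query = "TCGTACGTACTTACGTACGTC"
        status, _ = classify_known_novel(query, self.REFS)
        assert status == "novel"

    def test_shifted_by_one_is_known(self):
        query = self.REFS["mir1"][1:]  # length diff 1, 0 internal mismatches
        status, ref = classify_known_novel(query, self.REFS)
        assert (status, ref) == ("known", "mir1")

    def test_length_difference_over_two_is_novel(self):
        query = self.REFS["mir1"][3:]
        status, _ = classify_known_novel(query, self.REFS)
        assert status == "novel"

    def test_empty_reference_all_novel(self):
        status, ref = classify_known_novel("A" * 21, {})
        assert (status, ref) == ("novel", None)


class TestDiscovery:
    def test_planted_hairpins_recovered(self, sim, tags, triage):
        _cfg, refs, features, truth = sim
        total = {}
        for lib_tags in tags.values():
            for s, c in lib_tags.items():
                total[s] = total.get(s, 0) + c
        calls = discover(
            refs.genome, triage.genome_hits, total,
            mature_references={l.locus_id: l.mature for l in truth.of_class("mirna")},
        )
        keys = {c.candidate.key_sequence for c in calls}
        recovered = 0
        for locus in truth.of_class("mirna"):
            variants = {locus.mature, locus.mature[:-1]}
            if any(k in variants or locus.mature in k for k in keys):
                recovered += 1
        assert recovered == len(truth.of_class("mirna"))
        assert all(c.size_class in (20, 21, 22) for c in calls)

    def test_size_restriction_never_increases_calls(self, sim, tags, triage):
        _cfg, refs, _features, truth = sim
        total = {s: 1 for s in triage.genome_hits}
        all_sizes = discover(refs.genome, triage.genome_hits, total, size_classes=None)
        restricted = discover(
            refs.genome, triage.genome_hits, total, size_classes=(20, 21, 22)
        )
        assert len(restricted) <= len(all_sizes)
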