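"""Local alignment and flank-element detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgh import (AlignScoring, detect_direct_repeats, detect_same_is,
                  detect_trna_repeats, sw_align, tabulate_flanks)
from icgh.clusters import LCRCluster
from icgh.flanks import FlankReport, classify_cluster
from icgh.genome import AnnotatedGenome, feature_frame
from icgh.seqs import random_seq


def oracle_best_local(a: str, b: str, sc: AlignScoring) -> int:
    """Best affine-gap global score over all substring pairs (prefix cells of
    a suffix-pair global DP enumerate every end pair)."""
    best = 0
    NEG = -10**9
    for i in range(len(a)):
        for k in range(len(b)):
            sa, sb = a[i:], b[k:]
            n, m = len(sa), len(sb)
            M = [[NEG] * (m + 1) for _ in range(n + 1)]
            E = [[NEG] * (m + 1) for _ in range(n + 1)]
            F = [[NEG] * (m + 1) for _ in range(n + 1)]
            M[0][0] = 0
            for x in range(1, n + 1):
                F[x][0] = sc.gap_open + x * sc.gap_extend
            for y in range(1, m + 1):
                E[0][y] = sc.gap_open + y * sc.gap_extend
            for x in range(1, n + 1):
                for y in range(1, m + 1):
                    match = (sa[x - 1] == sb[y - 1] and sa[x - 1] in "ACGT")
                    s = sc.match if match else sc.mismatch
                    M[x][y] = max(M[x - 1][y - 1], E[x - 1][y - 1],
                                  F[x - 1][y - 1]) + s
                    E[x][y] = max(E[x][y - 1], M[x][y - 1] + sc.gap_open,
                                  F[x][y - 1] + sc.gap_open) + sc.gap_extend
                    F[x][y] = max(F[x - 1][y], M[x - 1][y] + sc.gap_open,
                                  E[x - 1][y] + sc.gap_open) + sc.gap_extend
            best = max(best, max(max(max(r) for r in M),
                                 max(max(r) for r in E),
                                 max(max(r) for r in F)))
    return best


class TestSwAlign:
    def test_identical_ten_mers_score_perfectly(self):
        aln = sw_align("ACGTACGTAC", "ACGTACGTAC")
        assert aln.score == 20
        assert aln.length == 10 and aln.identity == 1.0

    def test_no_positive_pair_gives_empty_alignment(self):
        aln = sw_align("AAAA", "CCCC")
        assert aln.score == 0 and aln.length == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sw_align("", "ACGT")

    def test_n_never_matches(self):
        assert sw_align("ACGNNNGT", "ACGNNNGT").score < 16
        assert sw_align("NNNN", "NNNN").score == 0

    def test_gap_costs_are_affine(self):
        # two 6-mers bridged by a 2-base gap in one sequence
        aln = sw_align("ACGTGGCCATTG", "ACGTGGAACCATTG")
        assert aln.score == 12 * 2 + (-5) + 2 * (-2)
        assert aln.length == 14

    def test_matches_exhaustive_oracle(self):
        sc = AlignScoring()
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = random_seq(int(rng.integers(1, 13)), 0.5, rng)
            b = random_seq(int(rng.integers(1, 13)), 0.5, rng)
            assert sw_align(a, b, sc).score == oracle_best_local(a, b, sc)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=20),
           st.text(alphabet="ACGT", min_size=1, max_size=20))
    def test_score_symmetry(self, a, b):
        assert sw_align(a, b).score == sw_align(b, a).score


def _island_genome(rng, flank_style, window_gap=30):
    """A linear genome with a 2-gene 'island' whose flanks carry the element."""
    trna = random_seq(80, 0.5, rng)
    is_core = random_seq(600, 0.5, rng)
    rep = random_seq(20, 0.5, rng)
    left_pad = random_seq(1200, 0.5, rng)
    right_pad = random_seq(1200, 0.5, rng)
    island = random_seq(2000, 0.5, rng)

    rows = []
    if flank_style == "trna_repeat":
        left_el, right_el = trna, trna
    elif flank_style == "direct_repeat":
        left_el, right_el = rep, rep
    elif flank_style == "same_is":
        from icgh.seqs import mutate

        left_el, right_el = mutate(is_core, 0.13, rng), mutate(is_core, 0.13, rng)
    else:
        left_el, right_el = "", ""
    gap_l = random_seq(window_gap, 0.5, rng)
    gap_r = random_seq(window_gap, 0.5, rng)
    seq = left_pad + left_el + gap_l + island + gap_r + right_el + right_pad
    start = len(left_pad)
    span = (start + len(left_el) + window_gap,
            start + len(left_el) + window_gap + len(island))
    if flank_style == "trna_repeat":
        rows.append({"feature_id": "tA", "kind": "tRNA", "start": start,
                     "end": start + 80, "strand": "+", "family": None,
                     "origin": "native"})
        r0 = span[1] + window_gap
        rows.append({"feature_id": "tB", "kind": "tRNA", "start": r0,
                     "end": r0 + 80, "strand": "+", "family": None,
                     "origin": "planted"})
    if flank_style == "same_is":
        rows.append({"feature_id": "isA", "kind": "IS", "start": start,
                     "end": start + 600, "strand": "+", "family": "IS3",
                     "origin": "native"})
        r0 = span[1] + window_gap
        rows.append({"feature_id": "isB", "kind": "IS", "start": r0,
                     "end": r0 + 600, "strand": "+", "family": "IS3",
                     "origin": "native"})
    genome = AnnotatedGenome(id="ref", seq=seq, features=feature_frame(rows),
                             circular=False)
    cluster = LCRCluster("c1", "q", ("gA", "gB"), 2, span[0], span[1])
    return genome, cluster


class TestDetectors:
    def test_trna_repeat_found_at_both_ends(self, rng):
        genome, cluster = _island_genome(rng, "trna_repeat")
        flag, tid = detect_trna_repeats(cluster, genome)
        assert flag and tid in {"tA", "tB"}

    def test_trna_at_one_end_only_is_not_enough(self, rng):
        genome, cluster = _island_genome(rng, "trna_repeat")
        # overwrite the right-hand copy (at span end + 30, 80 bp) with random
        # sequence and drop its annotation: no copy remains on that side
        feats = genome.features[genome.features.feature_id != "tB"]
        seq = (genome.seq[:cluster.end + 30] + random_seq(80, 0.5, rng)
               + genome.seq[cluster.end + 110:])
        one_sided = AnnotatedGenome("ref", seq, feats.reset_index(drop=True),
                                    circular=False)
        flag, _ = detect_trna_repeats(cluster, one_sided)
        assert not flag

    def test_no_trna_annotation_means_false(self, rng):
        genome, cluster = _island_genome(rng, "direct_repeat")
        assert detect_trna_repeats(cluster, genome) == (False, None)

    def test_direct_repeat_recovered(self, rng):
        genome, cluster = _island_genome(rng, "direct_repeat")
        flag, aln = detect_direct_repeats(cluster, genome)
        assert flag
        assert aln.length >= 20 and aln.identity == 1.0

    def test_identical_windows_are_a_direct_repeat(self, rng):
        block = random_seq(2000, 0.5, rng)
        seq = block + random_seq(500, 0.5, rng) + block
        genome = AnnotatedGenome("ref", seq, feature_frame([]), circular=False)
        cluster = LCRCluster("c", "q", (), 2, 2000, 2500)
        flag, aln = detect_direct_repeats(cluster, genome, window=2000)
        assert flag and aln.identity == 1.0

    def test_trna_derived_repeats_are_excluded(self, rng):
        genome, cluster = _island_genome(rng, "trna_repeat")
        flag, _ = detect_direct_repeats(cluster, genome, window=150)
        assert not flag  # the tRNA copies are masked out of this class

    def test_same_is_requires_shared_family(self, rng):
        genome, cluster = _island_genome(rng, "same_is")
        assert detect_same_is(cluster, genome) == (True, "IS3")
        feats = genome.features.copy()
        feats.loc[feats.feature_id == "isB", "family"] = "IS110"
        other = AnnotatedGenome("ref", genome.seq, feats, circular=False)
        assert detect_same_is(cluster, other) == (False, None)

    def test_diverged_is_pair_is_not_a_direct_repeat(self, rng):
        genome, cluster = _island_genome(rng, "same_is")
        flag, _ = detect_direct_repeats(cluster, genome, window=700)
        assert not flag

    def test_window_monotonicity(self, rng):
        genome, cluster = _island_genome(rng, "trna_repeat")
        for w in (500, 1000, 2000, 4000):
            assert detect_trna_repeats(cluster, genome, window=w)[0]
        genome2, cluster2 = _island_genome(rng, "same_is")
        for w in (800, 2000, 4000):
            assert detect_same_is(cluster2, genome2, window=w)[0]


class TestTabulate:
    def _report(self, cid, span, trna=False, direct=False, sameis=False):
        return FlankReport(cluster_id=cid, span=span, trna_repeat=trna,
                           trna_id=None, direct_repeat=direct, repeat_length=0,
                           repeat_identity=0.0, same_is=sameis, is_family=None)

    def test_empty(self):
        t = tabulate_flanks([])
        assert t.to_dict() == {"total": 0, "trna_repeats": 0,
                               "direct_repeats": 0, "same_is": 0}

    def test_category_counts(self):
        reports = [self._report("a", (0, 10), trna=True),
                   self._report("b", (20, 30), direct=True),
                   self._report("c", (40, 50))]
        assert tabulate_flanks(reports).to_dict() == {
            "total": 3, "trna_repeats": 1, "direct_repeats": 1, "same_is": 0}

    def test_identical_spans_deduplicate_across_queries(self):
        reports = [self._report("q1_c", (0, 10), trna=True),
                   self._report("q2_c", (0, 10), sameis=True)]
        t = tabulate_flanks(reports)
        assert t["total"] == 1
        assert t["trna_repeats"] == 1 and t["same_is"] == 1
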