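"""Mapper and SAM-ingestion contracts, including the naive-scan oracle."""

import numpy as np
import pytest

from icgh import MapperConfig, load_alignments, map_reads
from icgh.mapping import find_hits
from icgh.seqs import encode, random_seq, revcomp, revcomp_codes


def naive_hits(read: np.ndarray, ref: np.ndarray, max_mm: int) -> set:
    """All-positions ungapped scan, both strands; N never matches."""
    L, n = read.size, ref.size
    out = set()
    if L > n:
        return out
    wins = np.lib.stride_tricks.sliding_window_view(ref, L)
    for strand, rc in enumerate((read, revcomp_codes(read))):
        mm = ((wins != rc) | (wins >= 4) | (rc >= 4)).sum(axis=1)
        out |= {(int(p), strand) for p in np.flatnonzero(mm <= max_mm)}
    return out


def _sam(tmp_path, lines, ref_len=1000, name="ref"):
    path = tmp_path / "t.sam"
    header = f"@HD\tVN:1.6\n@SQ\tSN:{name}\tLN:{ref_len}\n"
    path.write_text(header + "".join(line + "\n" for line in lines))
    return path


class TestLoadAlignments:
    def test_empty_file_gives_zero_mask(self, tmp_path):
        mask = load_alignments(_sam(tmp_path, []), 1000, "ref")
        assert mask.covered.sum() == 0

    def test_single_read_covers_its_span(self, tmp_path):
        line = "r1\t0\tref\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*"
        mask = load_alignments(_sam(tmp_path, [line]), 1000, "ref")
        assert mask.covered.sum() == 50
        assert mask.covered[100:150].all()

    def test_overlapping_reads_union(self, tmp_path):
        lines = ["r1\t0\tref\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*",
                 "r2\t0\tref\t121\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*"]
        mask = load_alignments(_sam(tmp_path, lines), 1000, "ref")
        assert mask.covered.sum() == 70

    def test_secondary_unmapped_and_clips_ignored(self, tmp_path):
        lines = ["r1\t256\tref\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*",
                 "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t*",
                 "r3\t0\tref\t501\t60\t10S40M\t*\t0\t0\t" + "A" * 50 + "\t*"]
        mask = load_alignments(_sam(tmp_path, lines), 1000, "ref")
        assert mask.covered.sum() == 40  # only the 40M block of r3

    def test_length_mismatch_raises(self, tmp_path):
        with pytest.raises(ValueError, match="length"):
            load_alignments(_sam(tmp_path, [], ref_len=999), 1000, "ref")


class TestMapReads:
    def test_reverse_complement_read_covers_origin(self, rng):
        ref = random_seq(300, 0.5, rng)
        read = revcomp(ref[:50])
        mask = map_reads([read], ref)
        assert mask.covered[:50].all()
        assert mask.covered.sum() == 50

    def test_foreign_read_contributes_nothing(self, rng):
        ref = random_seq(500, 0.5, rng)
        foreign = random_seq(50, 0.5, np.random.default_rng(999))
        mask = map_reads([foreign], ref)
        assert mask.covered.sum() == 0

    def test_hit_set_equals_naive_scan(self):
        cfg = MapperConfig()
        for case in range(20):
            rng = np.random.default_rng(500 + case)
            n = int(rng.integers(200, 2001))
            ref = encode(random_seq(n, 0.5, rng))
            for _ in range(10):
                p = int(rng.integers(0, n - 49))
                read = ref[p:p + 50].copy()
                k = int(rng.integers(0, 5))
                idx = rng.integers(0, 50, k)
                read[idx] = (read[idx] + rng.integers(1, 4, k)) % 4
                if rng.random() < 0.5:
                    read = revcomp_codes(read)
                got = {(h[0], h[1]) for h in find_hits(read, ref, cfg)}
                assert got == naive_hits(read, ref, cfg.max_mismatches)

    def test_mismatch_monotonicity(self, rng):
        ref = encode(random_seq(800, 0.5, rng))
        read = ref[100:150].copy()
        read[[5, 20, 35]] = (read[[5, 20, 35]] + 1) % 4
        hits = {}
        for m in range(4):
            cfg = MapperConfig(max_mismatches=m)
            hits[m] = {(h[0], h[1]) for h in find_hits(read, ref, cfg)}
        for m in range(3):
            assert hits[m] <= hits[m + 1]

    def test_adding_reads_never_uncovers(self, rng):
        ref = random_seq(1000, 0.5, rng)
        reads = [ref[i:i + 50] for i in range(0, 500, 37)]
        prev = np.zeros(1000, dtype=bool)
        for k in range(1, len(reads) + 1):
            mask = map_reads(reads[:k], ref)
            assert (prev <= mask.covered).all()
            prev = mask.covered

    def test_best_only_keeps_single_location(self, rng):
        unit = random_seq(60, 0.5, rng)
        ref = unit + random_seq(100, 0.5, rng) + unit  # exact repeat
        read = unit[:50]
        multi = map_reads([read], ref, MapperConfig(count_multimappers=True))
        best = map_reads([read], ref, MapperConfig(count_multimappers=False))
        assert multi.covered.sum() == 100
        assert best.covered.sum() == 50
        assert best.covered[:50].all()  # leftmost tie-break

    def test_mask_matches_own_sam_output(self, small_genome, tmp_path):
        from icgh.simulate import ReadSimSpec, simulate_reads

        rs = simulate_reads(small_genome.seq,
                            ReadSimSpec(depth=1.0, sub_error_rate=0.01, seed=6))
        for multi in (True, False):
            sam = tmp_path / f"out_{multi}.sam"
            mask = map_reads(rs, small_genome,
                             MapperConfig(count_multimappers=multi), sam_path=sam)
            again = load_alignments(sam, len(small_genome), small_genome.id)
            assert (mask.covered == again.covered).all()

    def test_deep_coverage_saturates(self, small_genome):
        from icgh.simulate import ReadSimSpec, simulate_reads

        rs = simulate_reads(small_genome.seq, ReadSimSpec(depth=20.0, seed=1))
        mask = map_reads(rs, small_genome)
        assert mask.covered_fraction > 0.999
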