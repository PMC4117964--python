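"""Generator contracts: determinism, frame, conservation, read statistics."""

import numpy as np
import pytest

from icgh import (Deletion, EditPlan, GenomeSpec, Insertion, apply_edits,
                  dissect, generate_reference)
from icgh.codons import STOP_CODONS
from icgh.seqs import revcomp
from icgh.simulate import ReadSimSpec, simulate_reads


def _tiny_spec(**kw):
    base = dict(n_genes=2, mean_gene_len=300, mean_igr_len=100, seed=1,
                circular=False)
    base.update(kw)
    return GenomeSpec(**base)


class TestGenerateReference:
    def test_two_gene_layout_and_frame(self):
        g = generate_reference(_tiny_spec())
        genes = g.features[g.features.kind == "gene"]
        assert len(genes) == 2
        assert ((genes.end - genes.start) % 3 == 0).all()

    def test_byte_identical_under_seed(self, tmp_path):
        for i, sub in enumerate(["a", "b"]):
            d = tmp_path / sub
            d.mkdir()
            g = generate_reference(_tiny_spec())
            g.to_fasta(d / "ref.fasta")
            g.to_gff3(d / "ref.gff3")
        assert (tmp_path / "a/ref.fasta").read_bytes() == (tmp_path / "b/ref.fasta").read_bytes()
        assert (tmp_path / "a/ref.gff3").read_bytes() == (tmp_path / "b/ref.gff3").read_bytes()

    def test_dissection_of_200_gene_genome(self):
        g = generate_reference(GenomeSpec(n_genes=200, seed=7, circular=False))
        segs = dissect(g)
        assert (segs.kind != "IGR").sum() == 200
        assert len(segs) == 401  # gene and IGR segments strictly alternate

    def test_cds_frame_and_no_internal_stops(self, small_genome):
        genes = small_genome.features[small_genome.features.kind == "gene"]
        for fid in genes.feature_id:
            cds = small_genome.feature_seq(fid)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in STOP_CODONS
            internal = {cds[i:i + 3] for i in range(3, len(cds) - 3, 3)}
            assert not internal & set(STOP_CODONS)

    @pytest.mark.parametrize("bad", [dict(n_genes=0), dict(mean_gene_len=-1),
                                     dict(mean_igr_len=0), dict(gc_background=1.5)])
    def test_rejects_invalid_spec(self, bad):
        with pytest.raises(ValueError):
            GenomeSpec(**{**dict(n_genes=5), **bad})


class TestApplyEdits:
    def test_empty_plan_is_identity(self, small_genome):
        q, manifest = apply_edits(small_genome, EditPlan())
        assert q == small_genome.seq
        assert not manifest.fully_deleted and not manifest.insertions
        assert manifest.expected_size == len(small_genome)

    def test_single_gene_deletion_arithmetic(self, small_genome):
        g = small_genome.gene_features().iloc[5]
        plan = EditPlan(deletions=(Deletion(int(g.start), int(g.end),
                                            kind="isolated"),))
        q, manifest = apply_edits(small_genome, plan)
        assert len(q) == len(small_genome) - (g.end - g.start)
        assert manifest.fully_deleted == {g.feature_id}
        assert not manifest.partially_deleted

    def test_partial_overlap_is_recorded(self, small_genome):
        g = small_genome.gene_features().iloc[5]
        plan = EditPlan(deletions=(Deletion(int(g.start) + 30, int(g.end) + 10),))
        _, manifest = apply_edits(small_genome, plan)
        assert g.feature_id in manifest.partially_deleted

    def test_overlapping_deletions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EditPlan(deletions=(Deletion(10, 100), Deletion(50, 200)))

    def test_insertion_inside_gene_rejected(self, small_genome):
        g = small_genome.gene_features().iloc[0]
        plan = EditPlan(insertions=(Insertion(anchor=int(g.start) + 10, length=500),))
        with pytest.raises(ValueError, match="inside a gene"):
            apply_edits(small_genome, plan)

    def test_length_conservation_over_random_plans(self, small_genome, rng):
        genes = small_genome.gene_features()
        segs = dissect(small_genome)
        igrs = segs[(segs.kind == "IGR") & ~segs.wraps]
        for _ in range(10):
            i = int(rng.integers(len(genes) - 2))
            sel = genes.iloc[i:i + 2]
            anchor_row = igrs.iloc[int(rng.integers(len(igrs)))]
            anchor = int((anchor_row.start + anchor_row.end) // 2)
            dels = (Deletion(int(sel.iloc[0].start), int(sel.iloc[-1].end)),)
            ins = ()
            if not dels[0].start <= anchor < dels[0].end:
                ins = (Insertion(anchor=anchor, length=int(rng.integers(200, 2000))),)
            q, manifest = apply_edits(small_genome,
                                      EditPlan(deletions=dels, insertions=ins,
                                               seed=int(rng.integers(2**31))))
            assert len(q) == manifest.expected_size
            assert manifest.expected_size == (len(small_genome)
                                              - manifest.total_deleted_bp
                                              + manifest.total_inserted_bp)

    @pytest.mark.parametrize("style,check", [
        ("direct_repeat", "ends_equal"),
        ("trna_repeat", "ends_are_trna"),
    ])
    def test_insertion_flank_structure(self, small_genome, style, check):
        segs = dissect(small_genome)
        igr = segs[(segs.kind == "IGR") & ~segs.wraps].iloc[3]
        anchor = int((igr.start + igr.end) // 2)
        plan = EditPlan(insertions=(Insertion(anchor=anchor, length=1000,
                                              flank_style=style),), seed=9)
        q, manifest = apply_edits(small_genome, plan)
        rec = manifest.insertions[0]
        inserted = q[rec["query_start"]:rec["query_end"]]
        if check == "ends_equal":
            assert inserted[:20] == inserted[-20:]
        else:
            trnas = small_genome.features[small_genome.features.kind == "tRNA"]
            tseqs = {small_genome.seq[t.start:t.end] for t in trnas.itertuples()}
            lengths = {len(s) for s in tseqs}
            assert any(inserted[:n] in tseqs and inserted[-n:] in tseqs
                       for n in lengths)


class TestSimulateReads:
    def test_read_count_formula(self):
        seq = "ACGT" * 1250  # 5,000 bp
        rs = simulate_reads(seq, ReadSimSpec(read_len=50, depth=1.0, seed=0))
        assert rs.n == 100

    def test_error_free_reads_are_exact_substrings(self, small_genome):
        rs = simulate_reads(small_genome.seq,
                            ReadSimSpec(depth=0.2, sub_error_rate=0.0, seed=4))
        for i in range(rs.n):
            read = "".join("ACGTN"[c] for c in rs.reads[i])
            src = small_genome.seq[rs.positions[i]:rs.positions[i] + rs.read_len]
            assert read == (src if rs.strands[i] == 0 else revcomp(src))

    def test_observed_error_rate_matches(self, small_genome):
        rate = 0.01
        rs = simulate_reads(small_genome.seq,
                            ReadSimSpec(depth=2.0, sub_error_rate=rate, seed=8))
        from icgh.seqs import encode, revcomp_codes

        codes = encode(small_genome.seq)
        mism = 0
        for i in range(rs.n):
            src = codes[rs.positions[i]:rs.positions[i] + rs.read_len]
            read = rs.reads[i] if rs.strands[i] == 0 else revcomp_codes(rs.reads[i])
            mism += int((src != read).sum())
        total = rs.n * rs.read_len
        observed = mism / total
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(observed - rate) < 3 * se

    def test_deterministic_and_validated(self, small_genome):
        spec = ReadSimSpec(depth=0.5, sub_error_rate=0.02, seed=3)
        a = simulate_reads(small_genome.seq, spec)
        b = simulate_reads(small_genome.seq, spec)
        assert (a.reads == b.reads).all() and (a.positions == b.positions).all()
        with pytest.raises(ValueError):
            ReadSimSpec(depth=0)
        with pytest.raises(ValueError):
            simulate_reads("ACGT", ReadSimSpec(read_len=50, depth=1))

    def test_fastq_round_trip(self, small_genome, tmp_path):
        rs = simulate_reads(small_genome.seq, ReadSimSpec(depth=0.05, seed=2))
        path = tmp_path / "reads.fastq"
        rs.to_fastq(path)
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(path), "fastq"))
        assert len(recs) == rs.n
        assert str(recs[0].seq) == next(rs.sequences())
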