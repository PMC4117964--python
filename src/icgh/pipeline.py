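"""End-to-end orchestration: file-based pipeline runs and the synthetic demo.

:func:`run_pipeline` drives the complete analysis from files (reference
FASTA + GFF3, per-query FASTQ reads or SAM/BAM alignments) and writes the
summary artifacts: per-query coverage tables, LCR summary, Venn partition,
cluster and flank tables, gene properties, histograms/tracks and a run
manifest.

:func:`make_demo` is the self-contained worked example: it generates a
~200-gene annotated reference, derives four query genomes with known edit
plans of increasing severity (no loss; ~5% of genes deleted; ~15%; ~30% plus
foreign insertions), simulates 50 bp reads at uniform depth, runs the whole
analysis, and scores recovery against the generator's truth manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusters import ClusterResult, cluster_size_distribution, clusters_to_frame, find_clusters
from .content import (LCRCallSet, expected_genome_size, nonredundant_partition,
                      position_track, summarize_query)
from .flanks import FlankReport, classify_cluster, tabulate_flanks
from .genome import AnnotatedGenome, GENE_KINDS, read_genome
from .geneprops import codon_weights, gene_property_table, group_contrast
from .mapping import CoverageMask, MapperConfig, load_alignments, map_reads
from .segmentation import (DEFAULT_LCR_THRESHOLD, call_lcr, coverage_rates, dissect,
                           rate_histogram, write_segment_table)
from .simulate import (Deletion, EditPlan, GenomeSpec, Insertion, ReadSimSpec,
                       TruthManifest, apply_edits, design_edit_plan,
                       generate_reference, plant_flank_elements, simulate_reads)

__all__ = ["RunConfig", "StageError", "run_pipeline", "make_demo", "DemoResult"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs written so far are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a file-based pipeline run."""

    reference_fasta: str
    reference_gff3: str
    queries: dict[str, dict]          # query id -> {"reads": path} | {"alignments": path}
    outdir: str
    lcr_threshold: float = DEFAULT_LCR_THRESHOLD
    seed_k: int = 18
    max_mismatches: int = 3
    count_multimappers: bool = True
    trna_window: int = 2000
    repeat_window: int = 150
    repeat_min_len: int = 15
    repeat_min_identity: float = 0.85
    rounding: str = "half_away_from_zero"
    circular: bool | None = None
    seed: int = 0

    def validate(self) -> None:
        for p in [self.reference_fasta, self.reference_gff3]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not self.queries:
            raise ValueError("at least one query is required")
        for qid, entry in self.queries.items():
            if not ({"reads", "alignments"} & set(entry)):
                raise ValueError(f"query {qid}: needs 'reads' or 'alignments'")
            path = entry.get("reads") or entry.get("alignments")
            if not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _analyze_query(qid: str, mask: CoverageMask, segments: pd.DataFrame,
                   genome: AnnotatedGenome, threshold: float,
                   trna_window: int, repeat_window: int,
                   repeat_min_len: int, repeat_min_identity: float):
    cov = call_lcr(coverage_rates(mask, segments), threshold)
    lcr = cov[cov.lcr_flag]
    gene_ids = frozenset(lcr.loc[lcr.kind.isin(GENE_KINDS), "segment_id"])
    callset = LCRCallSet(query_id=qid, reference_id=genome.id,
                         lcr_gene_ids=gene_ids,
                         lcr_segment_ids=frozenset(lcr.segment_id))
    clusters = find_clusters(cov, query_id=qid, circular=genome.circular)
    reports = [classify_cluster(c, genome, trna_window=trna_window,
                                repeat_window=repeat_window,
                                min_len=repeat_min_len,
                                min_identity=repeat_min_identity)
               for c in clusters.clusters]
    return cov, callset, clusters, reports


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis from files; returns a dict of result objects."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapper = MapperConfig(seed_k=config.seed_k, max_mismatches=config.max_mismatches,
                          count_multimappers=config.count_multimappers)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError(name, exc) from exc

    genome = stage("load_reference", read_genome, config.reference_fasta,
                   config.reference_gff3, circular=config.circular)
    segments = stage("dissect", dissect, genome)
    total_genes = len(genome.gene_features())

    results: dict = {"genome": genome, "segments": segments, "queries": {}}
    summaries, callsets, all_reports, all_clusters = [], [], [], []
    for qid, entry in config.queries.items():
        if "alignments" in entry:
            mask = stage(f"{qid}:load_alignments", load_alignments,
                         entry["alignments"], len(genome), genome.id)
        else:
            mask = stage(f"{qid}:map_reads", map_reads, entry["reads"], genome, mapper)
        cov, callset, clusters, reports = stage(
            f"{qid}:call", _analyze_query, qid, mask, segments, genome,
            config.lcr_threshold, config.trna_window, config.repeat_window,
            config.repeat_min_len, config.repeat_min_identity)
        write_segment_table(cov, outdir / f"coverage_{qid}.tsv")
        rate_histogram(cov).to_csv(outdir / f"histogram_{qid}.tsv", sep="\t", index=False)
        position_track(cov).to_csv(outdir / f"track_{qid}.tsv", sep="\t", index=False)
        summary = summarize_query(callset, total_genes, config.rounding)
        summaries.append((qid, summary.n_lcr_genes, total_genes,
                          f"{summary.pct_exact:.4f}", summary.pct_reported))
        callsets.append(callset)
        all_reports += reports
        all_clusters.append(clusters)
        results["queries"][qid] = {"mask": mask, "coverage": cov, "callset": callset,
                                   "clusters": clusters, "flank_reports": reports,
                                   "summary": summary}

    summary_df = pd.DataFrame(summaries, columns=["query_id", "n_lcr_genes",
                                                  "total_genes", "pct_exact",
                                                  "pct_reported"])
    summary_df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    results["summary"] = summary_df

    if len(callsets) >= 2:
        union_size, venn = stage("venn", nonredundant_partition, callsets)
        venn.to_csv(outdir / "venn.tsv", sep="\t", index=False)
        results["venn"] = (union_size, venn)

    cluster_frames = [clusters_to_frame(c) for c in all_clusters]
    pd.concat(cluster_frames, ignore_index=True).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    flank_rows = pd.DataFrame([r.__dict__ for r in all_reports])
    flank_rows.to_csv(outdir / "flank_reports.tsv", sep="\t", index=False)
    flank_table = tabulate_flanks(all_reports) if all_reports else tabulate_flanks([])
    flank_table.to_frame("count").to_csv(outdir / "flank_table.tsv", sep="\t")
    results["flank_table"] = flank_table

    props = stage("gene_properties", _gene_properties, genome, callsets)
    props.to_csv(outdir / "properties.tsv", sep="\t", index=False)
    results["properties"] = props

    manifest = {
        "icgh_version": __version__,
        "reference": genome.id,
        "n_segments": int(len(segments)),
        "total_genes": int(total_genes),
        "parameters": {k: v for k, v in vars(config).items()
                       if k not in ("queries", "outdir")},
        "queries": sorted(config.queries),
        "seed": config.seed,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return results


def _gene_properties(genome: AnnotatedGenome, callsets) -> pd.DataFrame:
    he = genome.features[(genome.features.kind == "gene")
                         & (genome.features.origin == "highly_expressed")]
    if not len(he):  # no designated set: fall back to all protein genes
        he = genome.features[genome.features.kind == "gene"]
    weights = codon_weights({fid: genome.feature_seq(fid) for fid in he.feature_id})
    union: set[str] = set()
    for cs in callsets:
        union |= set(cs.lcr_gene_ids)
    return gene_property_table(genome, weights, lcr_nonredundant=union)


# ---------------------------------------------------------------------------
# The worked example / benchmark
# ---------------------------------------------------------------------------

@dataclass
class QueryRun:
    query_id: str
    manifest: TruthManifest
    mask: CoverageMask
    coverage: pd.DataFrame
    callset: LCRCallSet
    clusters: ClusterResult
    flank_reports: list[FlankReport]
    planted_cluster_sizes: list[int]
    planted_isolated: int
    reads: object | None = None  # ReadSet, kept only on request


@dataclass
class DemoResult:
    reference: AnnotatedGenome
    segments: pd.DataFrame
    queries: dict[str, QueryRun]
    summary: pd.DataFrame
    venn: tuple[int, pd.DataFrame] | None
    properties: pd.DataFrame
    contrast: pd.DataFrame
    flank_table: pd.Series
    #: reference span of each flank-styled planted deletion, keyed by style
    planted_flank_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)


def _demo_design(n_genes: int):
    """Cluster/isolated deletion layout for the demo, scaled to genome size."""
    if n_genes >= 120:
        cluster_specs = [(2, "none"), (3, "none"), (4, "trna_repeat"), (5, "none"),
                         (6, "direct_repeat"), (8, "same_is"), (10, "none"),
                         (12, "none")]
        n_isolated = 10
        assign = {
            "q2_low": ([2, 3], 5),
            "q3_moderate": ([2, 4, 6, 8], 10),
            "q4_heavy": ([2, 3, 4, 5, 6, 8, 10, 12], 10),
        }
    else:
        cluster_specs = [(2, "trna_repeat"), (3, "direct_repeat"), (4, "same_is")]
        n_isolated = 3
        assign = {
            "q2_low": ([2], 1),
            "q3_moderate": ([2, 3], 2),
            "q4_heavy": ([2, 3, 4], 3),
        }
    return cluster_specs, n_isolated, assign


def make_demo(seed: int = 0, n_genes: int = 200, depth: float = 20.0,
              sub_error_rate: float = 0.01, lcr_threshold: float = DEFAULT_LCR_THRESHOLD,
              include_insertions: bool = True, outdir=None,
              keep_reads: bool = False) -> DemoResult:
    """Generate the synthetic benchmark, run the analysis, score truth recovery.

    Four query genomes are derived from one annotated reference: ``q1_minimal``
    (no structural loss, Casuarina-like), ``q2_low`` (~5% of genes deleted),
    ``q3_moderate`` (~15%), and ``q4_heavy`` (~30%, plus foreign insertions
    when ``include_insertions``).  Deletions remove planted foreign-origin
    gene blocks (low GC3, atypical codon usage), so LCR genes carry the
    horizontal-transfer signature by construction.
    """
    rng = np.random.default_rng(seed)
    cluster_specs, n_isolated, assign = _demo_design(n_genes)
    sizes = tuple(s for s, _ in cluster_specs) + (1,) * n_isolated
    spec = GenomeSpec(n_genes=n_genes, seed=int(rng.integers(2**31)),
                      foreign_block_sizes=sizes)
    reference0 = generate_reference(spec)
    full_plan = design_edit_plan(reference0, cluster_specs, n_isolated=n_isolated,
                                 seed=int(rng.integers(2**31)))
    reference, planted = plant_flank_elements(reference0, list(full_plan.deletions),
                                              seed=int(rng.integers(2**31)))
    by_size = {}
    isolated = []
    for d in planted:
        if d.kind == "clustered":
            by_size[d.n_genes] = d
        else:
            isolated.append(d)

    segments = dissect(reference)
    total_genes = len(reference.gene_features())
    mapper = MapperConfig()

    # insertion anchors: IGR midpoints well away from any planned deletion
    def free_anchor(used: list[int]) -> int | None:
        igrs = segments[(segments.kind == "IGR") & ~segments.wraps]
        for min_dist in (3000, 1500, 800):
            candidates = []
            for row in igrs.itertuples():
                mid = (row.start + row.end) // 2
                if (all(abs(mid - (d.start + d.end) // 2)
                        > (d.end - d.start) // 2 + min_dist for d in planted)
                        and all(abs(mid - u) > min_dist for u in used)):
                    candidates.append(mid)
            if candidates:
                return int(candidates[int(rng.integers(len(candidates)))])
        return None

    plans: dict[str, EditPlan] = {"q1_minimal": EditPlan(seed=int(rng.integers(2**31)))}
    for qid, (csizes, niso) in assign.items():
        dels = tuple(by_size[s] for s in csizes) + tuple(isolated[:niso])
        ins: tuple[Insertion, ...] = ()
        if include_insertions:
            if qid == "q4_heavy":
                used: list[int] = []
                built = []
                for length, style in [(4000, "direct_repeat"), (6000, "trna_repeat")]:
                    a = free_anchor(used)
                    if a is not None:
                        used.append(a)
                        built.append(Insertion(anchor=a, length=length,
                                               flank_style=style))
                ins = tuple(built)
            elif qid == "q3_moderate":
                a = free_anchor([])
                if a is not None:
                    ins = (Insertion(anchor=a, length=3000, flank_style="same_is"),)
        plans[qid] = EditPlan(deletions=dels, insertions=ins,
                              seed=int(rng.integers(2**31)))

    queries: dict[str, QueryRun] = {}
    summaries, callsets, all_reports = [], [], []
    for qid, plan in plans.items():
        qseq, manifest = apply_edits(reference, plan)
        manifest.query_id = qid
        reads = simulate_reads(qseq, ReadSimSpec(read_len=50, depth=depth,
                                                 sub_error_rate=sub_error_rate,
                                                 seed=int(rng.integers(2**31))),
                               source_id=qid)
        mask = map_reads(reads, reference, mapper)
        cov, callset, clusters, reports = _analyze_query(
            qid, mask, segments, reference, lcr_threshold,
            2000, 150, 15, 0.85)
        csizes, niso = assign.get(qid, ([], 0))
        queries[qid] = QueryRun(query_id=qid, manifest=manifest, mask=mask,
                                coverage=cov, callset=callset, clusters=clusters,
                                flank_reports=reports,
                                planted_cluster_sizes=sorted(csizes),
                                planted_isolated=niso,
                                reads=reads if keep_reads else None)
        summary = summarize_query(callset, total_genes)
        summaries.append((qid, summary.n_lcr_genes, total_genes, summary.pct_exact,
                          summary.pct_reported))
        callsets.append(callset)
        all_reports += reports

    summary_df = pd.DataFrame(summaries, columns=["query_id", "n_lcr_genes",
                                                  "total_genes", "pct_exact",
                                                  "pct_reported"])
    venn = nonredundant_partition(callsets) if len(callsets) >= 2 else None
    properties = _gene_properties(reference, callsets)
    try:
        contrast = group_contrast(properties)
    except ValueError:
        contrast = pd.DataFrame()
    flank_table = tabulate_flanks(all_reports)

    metrics = _score_demo(reference, segments, queries, total_genes)
    flank_spans = {d.flank_style: (d.start, d.end) for d in planted
                   if d.flank_style != "none"}
    unflanked = [(d.start, d.end) for d in planted
                 if d.flank_style == "none" and d.kind == "clustered"]
    result = DemoResult(reference=reference, segments=segments, queries=queries,
                        summary=summary_df, venn=venn, properties=properties,
                        contrast=contrast, flank_table=flank_table,
                        planted_flank_spans={**flank_spans,
                                             "unflanked": unflanked},
                        metrics=metrics)
    if outdir is not None:
        _write_demo(result, Path(outdir))
    return result


def _score_demo(reference, segments, queries, total_genes) -> dict:
    metrics: dict = {"per_query": {}}
    extremes, totals = 0, 0
    for qid, q in queries.items():
        truth = set(q.manifest.fully_deleted)
        called = set(q.callset.lcr_gene_ids)
        tp = len(truth & called)
        precision = tp / len(called) if called else 1.0
        recall = tp / len(truth) if truth else 1.0
        hist, independents = cluster_size_distribution(q.clusters)
        planted_hist = {}
        for s in q.planted_cluster_sizes:
            planted_hist[s] = planted_hist.get(s, 0) + 1
        rates = q.coverage.coverage_rate.to_numpy()
        extreme = int(((rates < 10) | (rates >= 90)).sum())
        extremes += extreme
        totals += rates.size
        expected = expected_genome_size(len(reference), q.coverage)
        deletion_only = len(reference) - q.manifest.total_deleted_bp
        tol = 0
        for d in q.manifest.deletions:
            members = segments[(segments.start >= d.start) & (segments.end <= d.end)
                               & ~segments.wraps]
            if len(members):
                tol += int(members.iloc[0].length + members.iloc[-1].length)
        metrics["per_query"][qid] = {
            "n_truth_deleted": len(truth), "n_called": len(called),
            "precision": precision, "recall": recall,
            "cluster_hist": hist, "planted_cluster_hist": planted_hist,
            "n_independent": independents, "planted_isolated": q.planted_isolated,
            "clusters_exact": hist == planted_hist and independents == q.planted_isolated,
            "pct_extreme_bins": 100.0 * extreme / rates.size,
            "expected_size": expected, "deletion_only_size": deletion_only,
            "size_error_bp": abs(expected - deletion_only), "size_tolerance_bp": tol,
        }
    metrics["pct_extreme_bins_all"] = 100.0 * extremes / totals if totals else 0.0
    metrics["min_precision"] = min(m["precision"] for m in metrics["per_query"].values())
    metrics["min_recall"] = min(m["recall"] for m in metrics["per_query"].values())
    return metrics


def _write_demo(result: DemoResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.reference.to_fasta(outdir / "reference.fasta")
    result.reference.to_gff3(outdir / "reference.gff3")
    result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    pd.concat([q.manifest.to_frame() for q in result.queries.values()],
              ignore_index=True).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for qid, q in result.queries.items():
        write_segment_table(q.coverage, outdir / f"coverage_{qid}.tsv")
    if result.venn is not None:
        result.venn[1].to_csv(outdir / "venn.tsv", sep="\t", index=False)
    result.properties.to_csv(outdir / "properties.tsv", sep="\t", index=False)
    if len(result.contrast):
        result.contrast.to_csv(outdir / "contrast.tsv", sep="\t", index=False)
    result.flank_table.to_frame("count").to_csv(outdir / "flank_table.tsv", sep="\t")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True, default=str)
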