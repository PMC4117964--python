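"""LCR gene clusters: maximal runs of consecutive low-coverage segments.

A maximal run of consecutive LCR segments is an *LCR gene cluster* if it
contains two or more LCR genes — a candidate deleted/inserted genomic island.
Runs holding exactly one LCR gene yield an *independent* LCR gene; runs of
LCR IGRs alone are recorded separately and form no cluster.

By default any non-LCR segment breaks a run (the strictest reading of a
consecutive array); ``igr_gap_tolerance`` optionally lets non-LCR IGRs up to
that many bases bridge two LCR stretches, for robustness studies.  On
circular genomes a run spanning the origin is joined.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["LCRCluster", "ClusterResult", "find_clusters",
           "cluster_size_distribution", "clusters_to_frame", "clusters_to_bed"]


@dataclass(frozen=True)
class LCRCluster:
    cluster_id: str
    query_id: str
    member_ids: tuple[str, ...]
    n_lcr_genes: int
    start: int
    end: int
    wraps: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ClusterResult:
    clusters: list[LCRCluster]
    independent_gene_ids: list[str]
    igr_only_runs: list[tuple[str, ...]]

    @property
    def total_lcr_genes_in_clusters(self) -> int:
        return sum(c.n_lcr_genes for c in self.clusters)


def find_clusters(flagged: pd.DataFrame, query_id: str = "query",
                  circular: bool = False,
                  igr_gap_tolerance: int = 0) -> ClusterResult:
    """Identify LCR gene clusters and independent LCR genes.

    ``flagged`` is a coverage table with ``lcr_flag``, ordered by ``rank``.
    Raises on unordered input.
    """
    if not len(flagged):
        return ClusterResult([], [], [])
    ranks = flagged["rank"].to_numpy()
    if not (ranks[1:] > ranks[:-1]).all():
        raise ValueError("segments must be ordered by rank")
    segs = list(flagged.itertuples())

    def bridges(seg) -> bool:
        return (not seg.lcr_flag and seg.kind == "IGR"
                and seg.length <= igr_gap_tolerance)

    runs: list[list] = []
    current: list = []
    for seg in segs:
        if seg.lcr_flag or (current and bridges(seg)):
            current.append(seg)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    # trim bridge segments from run ends (runs must start/end with LCR)
    def trim(run):
        while run and not run[0].lcr_flag:
            run.pop(0)
        while run and not run[-1].lcr_flag:
            run.pop()
        return run

    runs = [r for r in (trim(r) for r in runs) if r]

    # circular genomes: a run touching the last segment joins one touching the
    # first (unless they are the same run, i.e. everything is LCR)
    if circular and len(runs) >= 2:
        if runs[0][0].Index == segs[0].Index and runs[-1][-1].Index == segs[-1].Index:
            runs = [runs[-1] + runs[0]] + runs[1:-1]

    clusters, independents, igr_only = [], [], []
    cid = 0
    for run in runs:
        gene_members = [s for s in run if s.lcr_flag and s.kind != "IGR"]
        if len(gene_members) >= 2:
            cid += 1
            wraps = bool(run[0].start > run[-1].end or any(s.wraps for s in run))
            clusters.append(LCRCluster(
                cluster_id=f"{query_id}_c{cid:03d}", query_id=query_id,
                member_ids=tuple(s.segment_id for s in run),
                n_lcr_genes=len(gene_members),
                start=int(run[0].start), end=int(run[-1].end), wraps=wraps))
        elif len(gene_members) == 1:
            independents.append(gene_members[0].segment_id)
        else:
            igr_only.append(tuple(s.segment_id for s in run))
    return ClusterResult(clusters, independents, igr_only)


def cluster_size_distribution(result: ClusterResult) -> tuple[dict[int, int], int]:
    """Histogram of cluster sizes (keyed by LCR gene count) and the number of
    independent LCR genes."""
    hist: dict[int, int] = {}
    for c in result.clusters:
        hist[c.n_lcr_genes] = hist.get(c.n_lcr_genes, 0) + 1
    return dict(sorted(hist.items())), len(result.independent_gene_ids)


def clusters_to_frame(result: ClusterResult) -> pd.DataFrame:
    rows = [(c.cluster_id, c.query_id, c.start, c.end, c.wraps, c.n_lcr_genes,
             ",".join(c.member_ids)) for c in result.clusters]
    return pd.DataFrame(rows, columns=["cluster_id", "query_id", "start", "end",
                                       "wraps", "n_lcr_genes", "member_ids"])


def clusters_to_bed(result: ClusterResult, genome_id: str, path) -> None:
    """Write cluster spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in result.clusters:
            fh.write(f"{genome_id}\t{c.start}\t{c.end}\t{c.cluster_id}\t"
                     f"{c.n_lcr_genes}\t.\n")
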