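"""Per-query and cross-query genome-content summaries.

Covers the per-strain summary (LCR gene counts and percentages against the
reference gene total), the Venn-style nonredundant partition of LCR genes
across 2–4 query strains, expected genome sizes (reference size minus total
LCR segment length), and genome-position coverage tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = ["LCRCallSet", "QuerySummary", "summarize_query",
           "nonredundant_partition", "expected_genome_size", "position_track"]


@dataclass(frozen=True)
class LCRCallSet:
    """The LCR genes (and segments) called for one query against a reference."""

    query_id: str
    reference_id: str
    lcr_gene_ids: frozenset[str]
    lcr_segment_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class QuerySummary:
    query_id: str
    n_lcr_genes: int
    total_genes: int
    pct_exact: float
    pct_reported: float


def round_percentage(pct: float, rule: str = "half_away_from_zero") -> float:
    """Report a percentage: nearest integer, except values below 1% keep two
    decimals (so a 2-in-4569 call reports as 0.04, not 0)."""
    if pct < 0 or pct > 100:
        raise ValueError("percentage out of range")
    if pct == 0:
        return 0.0
    if pct < 1.0:
        return round(pct, 2)
    if rule == "half_away_from_zero":
        return float(math.floor(pct + 0.5))
    if rule == "half_even":
        return float(round(pct))
    raise ValueError(f"unknown rounding rule {rule!r}")


def summarize_query(callset_or_count, reference_total_genes: int,
                    rounding: str = "half_away_from_zero") -> QuerySummary:
    """Per-strain summary row: LCR gene count and percentage of reference genes."""
    if reference_total_genes <= 0:
        raise ValueError("reference_total_genes must be positive")
    if isinstance(callset_or_count, LCRCallSet):
        qid = callset_or_count.query_id
        n = len(callset_or_count.lcr_gene_ids)
    else:
        qid = "query"
        n = int(callset_or_count)
    pct = 100.0 * n / reference_total_genes
    return QuerySummary(query_id=qid, n_lcr_genes=n,
                        total_genes=reference_total_genes, pct_exact=pct,
                        pct_reported=round_percentage(pct, rounding))


def nonredundant_partition(callsets) -> tuple[int, pd.DataFrame]:
    """Venn partition of the nonredundant LCR gene union across queries.

    ``callsets`` is a list of :class:`LCRCallSet` or a mapping of query id to
    gene-id set.  Every union member is assigned to exactly one membership
    pattern; the returned frame has one row per non-empty pattern with its
    count and percentage of the union.  Patterns are computed on genes only.
    """
    if isinstance(callsets, dict):
        sets = {qid: frozenset(s) for qid, s in callsets.items()}
    else:
        refs = {cs.reference_id for cs in callsets}
        if len(refs) > 1:
            raise ValueError(f"callsets against mixed references: {sorted(refs)}")
        sets = {cs.query_id: cs.lcr_gene_ids for cs in callsets}
    if len(sets) < 2:
        raise ValueError("need at least two callsets")
    qids = list(sets)
    union = set().union(*sets.values())
    rows = []
    for k in range(len(qids), 0, -1):
        for members in combinations(qids, k):
            exact = set.intersection(*[set(sets[q]) for q in members])
            for other in qids:
                if other not in members:
                    exact -= sets[other]
            if exact:
                rows.append(("&".join(members), len(members), len(exact),
                             100.0 * len(exact) / len(union)))
    df = pd.DataFrame(rows, columns=["pattern", "n_queries", "count", "pct"])
    return len(union), df


def expected_genome_size(reference_size: int, lcr_segments) -> int:
    """Expected query genome size: reference size minus total LCR length.

    ``lcr_segments`` is a flagged coverage table (only ``lcr_flag`` rows are
    subtracted), or an iterable of segment lengths.
    """
    if isinstance(lcr_segments, pd.DataFrame):
        if "lcr_flag" in lcr_segments.columns:
            total = int(lcr_segments.loc[lcr_segments.lcr_flag, "length"].sum())
        else:
            total = int(lcr_segments["length"].sum())
    else:
        total = int(sum(lcr_segments))
    if total > reference_size:
        raise ValueError("total LCR length exceeds reference size")
    return reference_size - total


def position_track(coverage: pd.DataFrame) -> pd.DataFrame:
    """Ordered (rank, coverage_rate) series for genome-position bar plots."""
    if not len(coverage):
        return pd.DataFrame(columns=["rank", "coverage_rate"])
    out = coverage.sort_values("rank")[["rank", "coverage_rate"]]
    return out.reset_index(drop=True)
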