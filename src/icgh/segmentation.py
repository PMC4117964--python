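"""Genome dissection into gene/IGR segments and the coverage-rate statistic.

The reference is dissected into two kinds of segments: one gene segment per
protein-coding or RNA gene (feature extents exactly, no flank padding), and
one intergenic-region (IGR) segment per positive gap between consecutive
genes.  On circular genomes the leading and trailing gaps merge into a single
wrap-around IGR.

The coverage rate of a segment is the percentage of its nucleotides covered
by at least one mapped read — breadth, not depth.  Segments with a rate
strictly below the threshold (default 20%) are low-coverage-rate (LCR)
segments, inferred absent from the query genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, GENE_KINDS
from .mapping import CoverageMask

__all__ = ["dissect", "coverage_rates", "call_lcr", "rate_histogram",
           "write_segment_table", "read_segment_table"]

SEGMENT_COLUMNS = ["segment_id", "kind", "start", "end", "length", "rank", "wraps"]

DEFAULT_LCR_THRESHOLD = 20.0


def dissect(annotation, genome_length: int | None = None,
            circular: bool | None = None) -> pd.DataFrame:
    """Dissect a genome into ordered gene and IGR segments.

    ``annotation`` is an :class:`AnnotatedGenome` or a feature DataFrame (in
    which case ``genome_length`` and ``circular`` are required).  Gene
    segments keep their feature id; IGR ids are ``IGR_<left>-<right>`` after
    the flanking genes.  Overlapping genes both become full segments and the
    swallowed gap yields no IGR.  A wrap-around IGR (circular genomes) is
    stored with ``wraps=True``, ``start`` = last gene end, ``end`` = first
    gene start, and length ``genome_length - start + end``.
    """
    if isinstance(annotation, AnnotatedGenome):
        features = annotation.gene_features()
        genome_length = len(annotation)
        circular = annotation.circular if circular is None else circular
    else:
        features = annotation[annotation.kind.isin(GENE_KINDS)]
        if genome_length is None or circular is None:
            raise ValueError("genome_length and circular are required with a "
                             "feature table")
    if ((features.start < 0) | (features.end > genome_length)).any():
        raise ValueError("feature outside genome")
    if (features.end <= features.start).any():
        raise ValueError("feature with end <= start")

    features = features.sort_values(["start", "end"], kind="stable")
    rows = []

    def igr(start, end, left, right, wraps=False):
        length = (genome_length - start + end) if wraps else (end - start)
        rows.append((f"IGR_{left}-{right}", "IGR", int(start), int(end),
                     int(length), wraps))

    if not len(features):
        if genome_length > 0:
            if circular:
                # a featureless circle is one wrap-around IGR over everything
                rows.append(("IGR_origin-origin", "IGR", 0, genome_length,
                             genome_length, False))
            else:
                igr(0, genome_length, "start", "end")
    else:
        first = features.iloc[0]
        last_id, max_end = None, 0
        if not circular and first.start > 0:
            igr(0, first.start, "start", first.feature_id)
        for row in features.itertuples():
            gap = row.start - max_end
            if last_id is not None and gap > 0:
                igr(max_end, row.start, last_id, row.feature_id)
            rows.append((row.feature_id, row.kind, int(row.start), int(row.end),
                         int(row.end - row.start), False))
            if row.end > max_end:
                max_end = row.end
                last_id = row.feature_id
        trailing = genome_length - max_end
        if circular:
            wrap_len = trailing + first.start
            if wrap_len > 0:
                igr(max_end, first.start, last_id, first.feature_id, wraps=True)
        elif trailing > 0:
            igr(max_end, genome_length, last_id, "end")

    df = pd.DataFrame(rows, columns=["segment_id", "kind", "start", "end",
                                     "length", "wraps"])
    # genome order: by start of the segment; the wrap IGR sorts last
    df["_sort"] = np.where(df.wraps, genome_length, df.start)
    df = df.sort_values(["_sort", "end"], kind="stable").drop(columns="_sort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df[SEGMENT_COLUMNS].reset_index(drop=True)


def coverage_rates(mask: CoverageMask, segments: pd.DataFrame) -> pd.DataFrame:
    """Exact covered-base counts and coverage rates per segment.

    The rate is ``100 * covered_bases / length``; no rounding is applied.
    """
    n = len(mask)
    if len(segments) and int(segments.end.max()) > n:
        raise ValueError(f"segments extend beyond mask length {n}")
    cum = np.concatenate([[0], np.cumsum(mask.covered.astype(np.int64))])
    out = segments.copy()
    starts = out.start.to_numpy()
    ends = out.end.to_numpy()
    covered = cum[ends] - cum[starts]
    if out.wraps.any():
        w = out.wraps.to_numpy()
        covered[w] = (cum[n] - cum[starts[w]]) + cum[ends[w]]
    out["covered_bases"] = covered
    out["coverage_rate"] = 100.0 * covered / out.length.to_numpy()
    return out


def call_lcr(coverage: pd.DataFrame,
             threshold: float = DEFAULT_LCR_THRESHOLD) -> pd.DataFrame:
    """Flag low-coverage-rate segments: rate strictly below the threshold."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0,100]")
    out = coverage.copy()
    out["lcr_flag"] = out.coverage_rate < threshold
    return out


def rate_histogram(coverage: pd.DataFrame, bin_width: int = 10) -> pd.DataFrame:
    """Counts of segments per coverage-rate bin.

    Bins are ``[0,w), [w,2w), ..., [100-w, 100]`` — the last bin is closed so
    fully covered segments land in it.  Counts sum to the segment count.
    """
    if bin_width <= 0 or 100 % bin_width != 0:
        raise ValueError("bin_width must divide 100")
    edges = np.arange(0, 100 + bin_width, bin_width)
    rates = coverage.coverage_rate.to_numpy() if len(coverage) else np.empty(0)
    counts, _ = np.histogram(rates, bins=edges)
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                         "count": counts})


def write_segment_table(flagged: pd.DataFrame, path) -> None:
    """Export the flagged coverage table as TSV (1-based starts, 4-decimal rates)."""
    out = flagged.copy()
    out["start"] = out.start + 1
    out["coverage_rate"] = out.coverage_rate.map(lambda r: f"{r:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_segment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["start"] = df.start - 1
    df["coverage_rate"] = df.coverage_rate.astype(float)
    return df
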