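"""Flanking-element classification of LCR gene clusters.

Genomic islands integrate at tRNA genes and excise between direct repeats or
same-family IS pairs, so the ends of each LCR cluster are searched for three
element classes:

* a tRNA gene (or a high-identity copy of one) within a window of *both*
  cluster ends, in direct-repeat orientation;
* a generic direct repeat: the optimal local alignment between the two
  end-windows reaches the minimum length and identity, in the same
  orientation (tRNA-derived repeats are excluded from this class — annotated
  tRNA bases are masked before the search);
* same-family IS copies annotated in both end-windows.

The local aligner is an affine-gap Smith–Waterman (Gotoh) with a numba
kernel; the optimal score and one optimal alignment (deterministic
tie-break: smallest end coordinates) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .clusters import LCRCluster
from .genome import AnnotatedGenome, window_seq
from .seqs import encode

__all__ = ["AlignScoring", "SWAlignment", "sw_align", "detect_trna_repeats",
           "detect_direct_repeats", "detect_same_is", "FlankReport",
           "classify_cluster", "tabulate_flanks"]

DEFAULT_TRNA_WINDOW = 2000
#: direct repeats from excision abut the junctions; a tight window keeps the
#: chance of a spurious >=15 bp near-exact alignment between random windows low
DEFAULT_REPEAT_WINDOW = 150


@dataclass(frozen=True)
class AlignScoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class SWAlignment:
    """Optimal local alignment: score and the aligned interval pair.

    ``identity`` is matches / aligned columns (gap columns included);
    ``length`` is the number of aligned columns.
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    matches: int

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            eh = H[i, j - 1] + gap_open + gap_extend
            E[i, j] = e if e > eh else eh
            f = F[i - 1, j] + gap_extend
            fh = H[i - 1, j] + gap_open + gap_extend
            F[i, j] = f if f > fh else fh
            if a[i - 1] < 4 and a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:  # strict: first maximum in scan order = smallest (i, j)
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _sw_traceback(H, E, F, a, b, bi, bj, match, mismatch,
                  gap_open, gap_extend):  # pragma: no cover
    i, j = bi, bj
    columns = 0
    matches = 0
    state = 0  # 0=H, 1=E (gap in a), 2=F (gap in b)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if a[i - 1] < 4 and a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                columns += 1
                if a[i - 1] < 4 and a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if E[i, j] == H[i, j - 1] + gap_open + gap_extend:
                state = 0
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] + gap_open + gap_extend:
                state = 0
            i -= 1
    return i, j, columns, matches


def sw_align(a: str | np.ndarray, b: str | np.ndarray,
             scoring: AlignScoring = AlignScoring()) -> SWAlignment:
    """Optimal local alignment of two sequences under affine gap scores.

    ``N`` never matches.  Returns score 0 and an empty alignment when no
    positive-scoring pair of substrings exists.  Raises on empty input.
    """
    ac = encode(a) if isinstance(a, str) else np.asarray(a, dtype=np.uint8)
    bc = encode(b) if isinstance(b, str) else np.asarray(b, dtype=np.uint8)
    if ac.size == 0 or bc.size == 0:
        raise ValueError("sw_align requires non-empty sequences")
    H, E, F, best, bi, bj = _sw_fill(ac, bc, scoring.match, scoring.mismatch,
                                     scoring.gap_open, scoring.gap_extend)
    if best == 0:
        return SWAlignment(0, 0, 0, 0, 0, 0, 0)
    i0, j0, columns, matches = _sw_traceback(
        H, E, F, ac, bc, bi, bj, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend)
    return SWAlignment(int(best), int(i0), int(bi), int(j0), int(bj),
                       int(columns), int(matches))


# ---------------------------------------------------------------------------
# End-window extraction
# ---------------------------------------------------------------------------

def _end_windows(cluster: LCRCluster, genome: AnnotatedGenome,
                 window: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(start, end) intervals of the windows outside both cluster ends.

    On circular genomes coordinates may wrap (handled by ``genome.window``);
    on linear genomes they are clamped.
    """
    left = (cluster.start - window, cluster.start)
    right = (cluster.end, cluster.end + window)
    if not genome.circular:
        left = (max(0, left[0]), left[1])
        right = (right[0], min(len(genome), right[1]))
    return left, right


def _features_in_window(genome: AnnotatedGenome, interval: tuple[int, int],
                        kind: str) -> pd.DataFrame:
    start, end = interval
    feats = genome.features[genome.features.kind == kind]
    n = len(genome)
    if genome.circular:
        start %= n
        end = start + (min(end - start, n))
    hits = feats[(feats.start < end) & (feats.end > start)]
    if genome.circular and end > n:  # wrapped tail [0, end-n)
        tail = feats[(feats.start < end - n) & (feats.end > 0)]
        hits = pd.concat([hits, tail]).drop_duplicates("feature_id")
    return hits


def _window_seq_masked(genome: AnnotatedGenome, interval: tuple[int, int],
                       mask_kinds: tuple[str, ...] = ()) -> str:
    """Window sequence with bases of the given feature kinds replaced by N."""
    if not mask_kinds:
        return genome.window(*interval)
    arr = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8).copy()
    feats = genome.features[genome.features.kind.isin(mask_kinds)]
    for f in feats.itertuples():
        arr[f.start : f.end] = ord("N")
    masked = arr.tobytes().decode("ascii")
    return window_seq(masked, genome.circular, *interval)


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_trna_repeats(cluster: LCRCluster, genome: AnnotatedGenome,
                        window: int = DEFAULT_TRNA_WINDOW,
                        min_identity: float = 0.9, min_coverage: float = 0.7,
                        scoring: AlignScoring = AlignScoring()
                        ) -> tuple[bool, str | None]:
    """tRNA direct repeat at both cluster ends.

    True iff a tRNA gene intersecting one end-window has a same-orientation
    copy (annotated or not) in the other end-window, with identity ≥
    ``min_identity`` over ≥ ``min_coverage`` of the tRNA length.  Comparing
    genome-forward sequences directly enforces direct-repeat orientation.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    left, right = _end_windows(cluster, genome, window)
    for own, other in ((left, right), (right, left)):
        other_seq = genome.window(*other)
        if not other_seq:
            continue
        for t in _features_in_window(genome, own, "tRNA").itertuples():
            tseq = genome.seq[t.start:t.end]
            aln = sw_align(tseq, other_seq, scoring)
            if not aln.length:
                continue
            coverage = (aln.a_end - aln.a_start) / len(tseq)
            if aln.identity >= min_identity and coverage >= min_coverage:
                return True, t.feature_id
    return False, None


def detect_direct_repeats(cluster: LCRCluster, genome: AnnotatedGenome,
                          window: int = DEFAULT_REPEAT_WINDOW,
                          min_len: int = 15, min_identity: float = 0.85,
                          scoring: AlignScoring = AlignScoring()
                          ) -> tuple[bool, SWAlignment | None]:
    """Generic direct repeat flanking the cluster.

    True iff the optimal local alignment of the two end-windows (same
    orientation; annotated tRNA bases masked, per the convention that tRNA
    repeats are tallied separately) spans ≥ ``min_len`` columns at identity ≥
    ``min_identity``.
    """
    if window <= 0 or min_len <= 0 or not 0 < min_identity <= 1:
        raise ValueError("invalid direct-repeat thresholds")
    left, right = _end_windows(cluster, genome, window)
    a = _window_seq_masked(genome, left, mask_kinds=("tRNA",))
    b = _window_seq_masked(genome, right, mask_kinds=("tRNA",))
    if not a or not b:
        return False, None
    aln = sw_align(a, b, scoring)
    ok = aln.length >= min_len and aln.identity >= min_identity
    return (True, aln) if ok else (False, aln if aln.length else None)


def detect_same_is(cluster: LCRCluster, genome: AnnotatedGenome,
                   window: int = DEFAULT_TRNA_WINDOW
                   ) -> tuple[bool, str | None]:
    """Same-family IS copies in both end-windows."""
    left, right = _end_windows(cluster, genome, window)
    fams_left = set(_features_in_window(genome, left, "IS").family.dropna())
    fams_right = set(_features_in_window(genome, right, "IS").family.dropna())
    shared = sorted(fams_left & fams_right)
    return (True, shared[0]) if shared else (False, None)


@dataclass(frozen=True)
class FlankReport:
    cluster_id: str
    span: tuple[int, int]
    trna_repeat: bool
    trna_id: str | None
    direct_repeat: bool
    repeat_length: int
    repeat_identity: float
    same_is: bool
    is_family: str | None


def classify_cluster(cluster: LCRCluster, genome: AnnotatedGenome,
                     trna_window: int = DEFAULT_TRNA_WINDOW,
                     repeat_window: int = DEFAULT_REPEAT_WINDOW,
                     min_len: int = 15, min_identity: float = 0.85,
                     scoring: AlignScoring = AlignScoring()) -> FlankReport:
    trna, tid = detect_trna_repeats(cluster, genome, trna_window, scoring=scoring)
    direct, aln = detect_direct_repeats(cluster, genome, repeat_window,
                                        min_len, min_identity, scoring)
    sameis, fam = detect_same_is(cluster, genome, trna_window)
    return FlankReport(cluster_id=cluster.cluster_id, span=cluster.span,
                       trna_repeat=trna, trna_id=tid, direct_repeat=direct,
                       repeat_length=aln.length if (direct and aln) else 0,
                       repeat_identity=aln.identity if (direct and aln) else 0.0,
                       same_is=sameis, is_family=fam)


def tabulate_flanks(reports: list[FlankReport]) -> pd.Series:
    """Flank-element class counts over nonredundant clusters.

    Clusters from different queries sharing an identical reference span count
    once; a cluster may satisfy several element classes (tRNA repeats are
    already excluded from the generic direct-repeat class by masking).
    """
    seen: dict[tuple[int, int], FlankReport] = {}
    for r in reports:
        prev = seen.get(r.span)
        if prev is None:
            seen[r.span] = r
        else:  # merge flags observed for the same span across queries
            seen[r.span] = FlankReport(
                cluster_id=prev.cluster_id, span=prev.span,
                trna_repeat=prev.trna_repeat or r.trna_repeat,
                trna_id=prev.trna_id or r.trna_id,
                direct_repeat=prev.direct_repeat or r.direct_repeat,
                repeat_length=max(prev.repeat_length, r.repeat_length),
                repeat_identity=max(prev.repeat_identity, r.repeat_identity),
                same_is=prev.same_is or r.same_is,
                is_family=prev.is_family or r.is_family)
    vals = list(seen.values())
    return pd.Series({
        "total": len(vals),
        "trna_repeats": sum(r.trna_repeat for r in vals),
        "direct_repeats": sum(r.direct_repeat for r in vals),
        "same_is": sum(r.same_is for r in vals),
    })
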