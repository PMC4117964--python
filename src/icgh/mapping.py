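"""Per-base coverage masks from reads or standard alignments.

Two routes produce a :class:`CoverageMask`:

* :func:`load_alignments` ingests SAM/BAM produced by any aligner; a base is
  covered iff at least one non-secondary, non-unmapped alignment block
  overlaps it (clipped bases do not cover).
* :func:`map_reads` is a built-in ungapped mapper sufficient for synthetic
  data.  Its contract is exact: a read maps at a reference position iff the
  full-length ungapped comparison there has at most ``max_mismatches``
  mismatches, on either strand.  Seeding is a pure accelerator — reads are
  split into ``max_mismatches + 1`` disjoint exact-match chunks (pigeonhole),
  so no valid location is ever missed and the hit set equals a naive
  all-positions scan.  ``seed_k`` caps the chunk length.

Multi-mapping reads contribute coverage at every passing location by default;
coverage *breadth* is the presence/absence signal, and dropping repeats would
spuriously flag multicopy genes as absent.  ``count_multimappers=False``
keeps one best location instead (fewest mismatches, ties broken by leftmost
position, forward strand first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import AnnotatedGenome
from .seqs import decode, encode, revcomp_codes

__all__ = ["CoverageMask", "MapperConfig", "map_reads", "load_alignments"]


@dataclass
class CoverageMask:
    """Per-base covered/uncovered state of one reference for one query."""

    genome_id: str
    covered: np.ndarray  # bool, length == reference length

    def __post_init__(self):
        self.covered = np.asarray(self.covered, dtype=bool)

    def __len__(self) -> int:
        return self.covered.size

    @property
    def covered_fraction(self) -> float:
        return float(self.covered.mean()) if self.covered.size else 0.0


@dataclass(frozen=True)
class MapperConfig:
    seed_k: int = 18
    max_mismatches: int = 3
    count_multimappers: bool = True

    def __post_init__(self):
        if self.seed_k < 1:
            raise ValueError("seed_k must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def _reference_codes(reference) -> tuple[str, np.ndarray]:
    if isinstance(reference, AnnotatedGenome):
        return reference.id, reference.codes
    if isinstance(reference, str):
        return "reference", encode(reference)
    raise TypeError("reference must be an AnnotatedGenome or a sequence string")


def _as_read_matrix(reads) -> tuple[list[str], list[np.ndarray]]:
    """Normalise read input to (names, encoded arrays)."""
    from .simulate import ReadSet

    if isinstance(reads, ReadSet):
        return list(reads.names()), [reads.reads[i] for i in range(reads.n)]
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        names, arrs = [], []
        for rec in SeqIO.parse(str(reads), "fastq"):
            names.append(rec.id)
            arrs.append(encode(str(rec.seq)))
        return names, arrs
    names, arrs = [], []
    for i, item in enumerate(reads):
        if isinstance(item, tuple):
            name, seq = item
        else:
            name, seq = f"read{i}", item
        names.append(name)
        arrs.append(encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8))
    return names, arrs


class _SeedIndex:
    """Sorted-array index of all ell-mers of the reference forward strand."""

    def __init__(self, codes: np.ndarray, ell: int):
        self.ell = ell
        self.n = codes.size
        if self.n < ell:
            self.sorted_codes = np.empty(0, dtype=np.int64)
            self.order = np.empty(0, dtype=np.int64)
            return
        windows = np.lib.stride_tricks.sliding_window_view(codes, ell)
        pw = (4 ** np.arange(ell - 1, -1, -1)).astype(np.int64)
        kcodes = windows.astype(np.int64) @ pw
        kcodes[(windows >= 4).any(axis=1)] = -1  # ambiguous bases never seed
        self.order = np.argsort(kcodes, kind="stable").astype(np.int64)
        self.sorted_codes = kcodes[self.order]

    def lookup(self, kcode: int) -> np.ndarray:
        if kcode < 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self.sorted_codes, kcode, side="left")
        hi = np.searchsorted(self.sorted_codes, kcode, side="right")
        return self.order[lo:hi]


def find_hits(read_codes: np.ndarray, ref_codes: np.ndarray, config: MapperConfig,
              index: _SeedIndex | None = None,
              rc_cache: np.ndarray | None = None) -> list[tuple[int, int, int]]:
    """All mapping locations of one read: (position, strand, mismatches).

    strand 0 = read matches the forward reference, 1 = its reverse complement
    does.  Exactly the locations a naive ≤``max_mismatches`` scan would find.
    """
    L = read_codes.size
    m = config.max_mismatches
    ell = min(config.seed_k, max(1, L // (m + 1)))
    if index is None or index.ell != ell:
        index = _SeedIndex(ref_codes, ell)
    pw = (4 ** np.arange(ell - 1, -1, -1)).astype(np.int64)
    hits: list[tuple[int, int, int]] = []
    n = ref_codes.size
    oriented = (read_codes, rc_cache if rc_cache is not None else revcomp_codes(read_codes))
    for strand, rc in enumerate(oriented):
        seen: set[int] = set()
        for chunk in range(m + 1):
            off = chunk * ell
            if off + ell > L:
                break
            window = rc[off : off + ell]
            if (window >= 4).any():
                continue
            kcode = int(window.astype(np.int64) @ pw)
            for pos in index.lookup(kcode):
                p = int(pos) - off
                if p < 0 or p + L > n or p in seen:
                    continue
                seen.add(p)
                block = ref_codes[p : p + L]
                mm = int(np.count_nonzero((block != rc) | (block >= 4) | (rc >= 4)))
                if mm <= m:
                    hits.append((p, strand, mm))
    return hits


def map_reads(reads, reference, config: MapperConfig = MapperConfig(),
              sam_path=None) -> CoverageMask:
    """Map reads onto the reference and return the union coverage mask.

    ``reads`` may be a :class:`~icgh.simulate.ReadSet`, a FASTQ path, or an
    iterable of sequences / (name, sequence) pairs.  If ``sam_path`` is given,
    every reported location is written as a SAM line (unmapped reads get a
    flag-4 record), so re-ingesting that file with :func:`load_alignments`
    reproduces the mask exactly.
    """
    ref_id, ref_codes = _reference_codes(reference)
    names, arrs = _as_read_matrix(reads)
    n = ref_codes.size
    diff = np.zeros(n + 1, dtype=np.int64)
    indexes: dict[int, _SeedIndex] = {}
    sam = open(sam_path, "w") if sam_path else None
    if sam:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        sam.write(f"@SQ\tSN:{ref_id}\tLN:{n}\n")
        sam.write("@PG\tID:icgh\tPN:icgh\n")
    try:
        for name, rc in zip(names, arrs):
            L = rc.size
            m = config.max_mismatches
            ell = min(config.seed_k, max(1, L // (m + 1)))
            if ell not in indexes:
                indexes[ell] = _SeedIndex(ref_codes, ell)
            hits = find_hits(rc, ref_codes, config, index=indexes[ell])
            if hits and not config.count_multimappers:
                hits = [min(hits, key=lambda h: (h[2], h[0], h[1]))]
            for p, strand, mm in hits:
                diff[p] += 1
                diff[p + L] -= 1
            if sam:
                if not hits:
                    sam.write(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{decode(rc)}\t*\n")
                for p, strand, mm in hits:
                    seq = decode(rc if strand == 0 else revcomp_codes(rc))
                    flag = 16 if strand == 1 else 0
                    sam.write(f"{name}\t{flag}\t{ref_id}\t{p + 1}\t60\t{L}M\t*\t0\t0"
                              f"\t{seq}\t*\tNM:i:{mm}\n")
    finally:
        if sam:
            sam.close()
    covered = np.cumsum(diff[:-1]) > 0
    return CoverageMask(genome_id=ref_id, covered=covered)


def load_alignments(path, reference_length: int,
                    reference_name: str | None = None) -> CoverageMask:
    """Coverage mask from a SAM/BAM file.

    A base is covered iff at least one non-secondary, non-unmapped alignment
    block overlaps it; soft/hard-clipped bases do not cover.  Raises
    ``ValueError`` on a reference name/length mismatch with the SAM header.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    diff = np.zeros(reference_length + 1, dtype=np.int64)
    ref_id = None
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for name, length in zip(fh.references, fh.lengths):
            if reference_name is not None and name != reference_name:
                continue
            if length != reference_length:
                raise ValueError(f"reference {name} length {length} != expected "
                                 f"{reference_length}")
            ref_id = name
        if ref_id is None and fh.nreferences:
            raise ValueError(f"reference {reference_name!r} not found in header")
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if reference_name is not None and aln.reference_name != reference_name:
                continue
            for start, end in aln.get_blocks():
                diff[start] += 1
                diff[min(end, reference_length)] -= 1
    covered = np.cumsum(diff[:-1]) > 0
    return CoverageMask(genome_id=ref_id or (reference_name or "reference"),
                        covered=covered)
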