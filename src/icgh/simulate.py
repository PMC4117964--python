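"""Synthetic annotated genomes, structural edits with ground truth, and reads.

The generator provides everything the downstream coverage analysis needs to be
tested against known truth: a reference genome of alternating gene/IGR
segments, query genomes derived from it by deleting clustered and isolated
genes and splicing in foreign DNA, and uniform-depth 50 bp reads with a small
substitution error rate.

Foreign coding sequence is drawn from a codon model whose third-position GC is
shifted down (default −15 percentage points) relative to the native model, so
the horizontally-acquired signature (low GC3, low CAI) is recoverable by
construction.  Flanking elements that mark excisable islands — direct repeats,
tRNA direct repeats, and same-family IS pairs — are spliced into the reference
around planned deletion runs by :func:`plant_flank_elements`.

All operations are bit-deterministic given their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import codons
from .genome import AnnotatedGenome, GENE_KINDS, feature_frame
from .seqs import decode, encode, mutate, random_seq, revcomp

__all__ = [
    "GenomeSpec", "Deletion", "Insertion", "EditPlan", "TruthManifest",
    "ReadSimSpec", "ReadSet", "generate_reference", "apply_edits",
    "plant_flank_elements", "design_edit_plan", "simulate_reads",
]

IS_FAMILIES = ("IS3", "IS110", "IS256", "IS21")

#: minimum segment sizes (the length draws are truncated here)
MIN_IGR_LEN = 30
MIN_GENE_LEN = 90


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic annotated reference genome."""

    n_genes: int
    mean_gene_len: int = 900
    mean_igr_len: int = 150
    gc_background: float = 0.7
    seed: int = 0
    circular: bool = True
    n_trna: int | None = None            # default: n_genes // 40 (0 below 20 genes)
    n_is: int | None = None              # default: n_genes // 25
    n_highly_expressed: int | None = None  # default: ~5% of genes (0 below 20)
    foreign_block_sizes: tuple[int, ...] = ()
    foreign_gc3_delta: float = -15.0     # percentage points relative to native GC3
    is_divergence: float = 0.22          # per-base divergence of IS copies from consensus

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.mean_gene_len <= 0 or self.mean_igr_len <= 0:
            raise ValueError("mean lengths must be positive")
        if not 0.0 < self.gc_background < 1.0:
            raise ValueError("gc_background must be in (0,1)")
        if any(s < 1 for s in self.foreign_block_sizes):
            raise ValueError("foreign block sizes must be >= 1")


def _truncated_geometric(rng, mean_extra: float, size=None):
    """Geometric-distributed non-negative extras with the given mean."""
    if mean_extra <= 0:
        return np.zeros(size or 1, dtype=np.int64) if size else 0
    p = 1.0 / (mean_extra + 1.0)
    draw = rng.geometric(p, size=size) - 1
    return draw


def _place_blocks(rng, n_slots: int, sizes: list[int], margin: int = 2,
                  gap: int = 2) -> list[tuple[int, int]]:
    """Place gene-index blocks of the given sizes, non-overlapping, separated
    by at least ``gap`` slots, at least ``margin`` slots from the ends."""
    if not sizes:
        return []
    order = rng.permutation(len(sizes))
    sizes_in_order = [sizes[i] for i in order]
    k = len(sizes_in_order)
    slack = n_slots - 2 * margin - sum(sizes_in_order) - gap * (k - 1)
    if slack < 0:
        raise ValueError("genome too small for the requested foreign blocks")
    # distribute the slack over the k+1 inter-block gaps
    extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    placements = []
    cursor = margin + int(extra[0])
    for size, e in zip(sizes_in_order, extra[1:]):
        placements.append((cursor, cursor + size))
        cursor += size + gap + int(e)
    # undo the shuffle so block i corresponds to sizes[i]
    out = [None] * k
    for slot, orig in enumerate(order):
        out[orig] = placements[slot]
    return out


def generate_reference(spec: GenomeSpec) -> AnnotatedGenome:
    """Build an annotated reference genome with alternating gene/IGR layout.

    Genes have a start codon, an in-frame body free of internal stops drawn
    from a codon-usage model, and a stop codon.  A configurable subset of gene
    slots is emitted as tRNA genes; IS elements are spliced into a subset of
    IGRs.  Foreign blocks (runs of consecutive genes drawn from the shifted
    codon model) are placed where requested and tagged ``origin=foreign``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n_trna = spec.n_trna if spec.n_trna is not None else (0 if n < 20 else max(2, n // 40))
    n_is = spec.n_is if spec.n_is is not None else n // 25
    n_he = (spec.n_highly_expressed if spec.n_highly_expressed is not None
            else (0 if n < 20 else max(2, round(0.05 * n))))

    native = codons.usage_model(spec.gc_background)
    highly = codons.usage_model(spec.gc_background, concentration=0.85)
    foreign_gc3 = min(0.95, max(0.05, spec.gc_background + spec.foreign_gc3_delta / 100.0))
    foreign = codons.usage_model(foreign_gc3)

    blocks = _place_blocks(rng, n, list(spec.foreign_block_sizes))
    foreign_slots: set[int] = set()
    for b0, b1 in blocks:
        foreign_slots.update(range(b0, b1))
    # slots adjacent to foreign blocks stay plain protein genes
    near_foreign = {s + d for s in foreign_slots for d in (-2, -1, 1, 2)}
    free = [i for i in range(n) if i not in foreign_slots and i not in near_foreign]
    rng.shuffle(free)
    if len(free) < n_trna + n_he:  # small genomes: allow slots near blocks
        extra = [i for i in range(n) if i in near_foreign and i not in foreign_slots]
        rng.shuffle(extra)
        free = free + extra
    trna_slots = set(free[:n_trna])
    he_slots = set(free[n_trna:n_trna + n_he])

    # IS elements live inside IGRs away from foreign blocks
    igr_candidates = [i for i in range(1, n)  # IGR i sits between gene i-1 and gene i
                      if not ({i - 1, i} & (foreign_slots | near_foreign))]
    rng.shuffle(igr_candidates)
    is_hosts = {}
    consensi = {fam: random_seq(int(rng.integers(700, 1001)), spec.gc_background, rng)
                for fam in IS_FAMILIES}
    for j, igr_idx in enumerate(sorted(igr_candidates[:n_is])):
        is_hosts[igr_idx] = IS_FAMILIES[int(rng.integers(len(IS_FAMILIES)))]

    mean_codons_extra = max(0.0, (spec.mean_gene_len - MIN_GENE_LEN) / 3.0)
    mean_igr_extra = max(0.0, spec.mean_igr_len - MIN_IGR_LEN)
    stop_codons = list(codons.STOP_CODONS)

    pieces: list[str] = []
    rows: list[dict] = []
    pos = 0

    def emit_igr(idx: int) -> None:
        nonlocal pos
        length = MIN_IGR_LEN + int(_truncated_geometric(rng, mean_igr_extra))
        seq = random_seq(length, spec.gc_background, rng)
        if idx in is_hosts:
            fam = is_hosts[idx]
            cut = int(rng.integers(10, length - 9))
            copy = mutate(consensi[fam], spec.is_divergence, rng)
            rows.append({"feature_id": f"is{idx:04d}", "kind": "IS",
                         "start": pos + cut, "end": pos + cut + len(copy),
                         "strand": "+-"[int(rng.integers(2))], "family": fam,
                         "origin": "native"})
            seq = seq[:cut] + copy + seq[cut:]
        pieces.append(seq)
        pos += len(seq)

    for i in range(n):
        emit_igr(i)
        strand = "+-"[int(rng.integers(2))]
        if i in trna_slots:
            length = int(rng.integers(72, 91))
            seq = random_seq(length, spec.gc_background, rng)
            fid, kind, origin = f"t{i + 1:04d}", "tRNA", "native"
        else:
            if i in foreign_slots:
                model, origin = foreign, "foreign"
            elif i in he_slots:
                model, origin = highly, "highly_expressed"
            else:
                model, origin = native, "native"
            n_codons = MIN_GENE_LEN // 3 + int(_truncated_geometric(rng, mean_codons_extra))
            cds = "ATG" + model.sample(n_codons - 2, rng) + stop_codons[int(rng.integers(3))]
            seq = cds if strand == "+" else revcomp(cds)
            fid, kind = f"g{i + 1:04d}", "gene"
        rows.append({"feature_id": fid, "kind": kind, "start": pos,
                     "end": pos + len(seq), "strand": strand, "family": None,
                     "origin": origin})
        pieces.append(seq)
        pos += len(seq)
    emit_igr(n)

    features = feature_frame(rows).sort_values("start", kind="stable").reset_index(drop=True)
    return AnnotatedGenome(id=f"synthref_s{spec.seed}", seq="".join(pieces),
                           features=features, circular=spec.circular)


# ---------------------------------------------------------------------------
# Structural edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Deletion:
    """A deleted interval on the reference, spanning whole segments."""

    start: int
    end: int
    kind: str = "clustered"          # "clustered" | "isolated"
    flank_style: str = "none"        # "none" | "direct_repeat" | "trna_repeat" | "same_is"
    n_genes: int = 0                 # gene-kind features fully inside the interval

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("deletion end must exceed start")
        if self.flank_style not in ("none", "direct_repeat", "trna_repeat", "same_is"):
            raise ValueError(f"unknown flank_style {self.flank_style!r}")


@dataclass(frozen=True)
class Insertion:
    """A foreign segment spliced into the query at a reference IGR position."""

    anchor: int
    length: int
    gc3_shift: float = -15.0         # percentage points vs the native model
    codon_bias_shift: float = 0.0    # fraction of codons drawn with bias erased
    flank_style: str = "none"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("insertion length must be positive")
        if self.flank_style not in ("none", "direct_repeat", "trna_repeat", "same_is"):
            raise ValueError(f"unknown flank_style {self.flank_style!r}")


@dataclass(frozen=True)
class EditPlan:
    deletions: tuple[Deletion, ...] = ()
    insertions: tuple[Insertion, ...] = ()
    seed: int = 0

    def __post_init__(self):
        dels = sorted(self.deletions, key=lambda d: d.start)
        for a, b in zip(dels, dels[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping deletions [{a.start},{a.end}) and "
                                 f"[{b.start},{b.end})")
        object.__setattr__(self, "deletions", tuple(dels))
        object.__setattr__(self, "insertions",
                           tuple(sorted(self.insertions, key=lambda i: i.anchor)))


@dataclass
class TruthManifest:
    """Ground-truth record of the edits that produced one query genome."""

    query_id: str
    reference_id: str
    reference_size: int
    expected_size: int
    fully_deleted: frozenset[str]
    partially_deleted: frozenset[str]
    deletions: tuple[Deletion, ...]
    insertions: tuple[dict, ...]     # ref_anchor, query_start, query_end, length, flank_style
    total_deleted_bp: int
    total_inserted_bp: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.deletions:
            rows.append((self.query_id, f"deletion_{d.kind}", "NA", d.start, d.end,
                         d.end - d.start, d.flank_style))
        for i in self.insertions:
            rows.append((self.query_id, "insertion", "NA", i["ref_anchor"],
                         i["ref_anchor"], i["length"], i["flank_style"]))
        for fid in sorted(self.fully_deleted):
            rows.append((self.query_id, "gene_deleted_full", fid, -1, -1, -1, "NA"))
        for fid in sorted(self.partially_deleted):
            rows.append((self.query_id, "gene_deleted_partial", fid, -1, -1, -1, "NA"))
        return pd.DataFrame(rows, columns=["query_id", "edit_type", "feature_id_or_NA",
                                           "ref_start", "ref_end", "length", "flank_style"])


def _foreign_segment(reference: AnnotatedGenome, ins: Insertion,
                     rng: np.random.Generator) -> str:
    """Generate the sequence spliced in for one insertion."""
    gc = float(np.isin(reference.codes, (1, 2)).mean())
    model = codons.usage_model(min(0.95, max(0.05, gc + ins.gc3_shift / 100.0)))
    flat = codons.usage_model(0.5)
    pieces, total = [], 0
    while total < ins.length:
        spacer = random_seq(int(rng.integers(40, 160)), gc, rng)
        n_codons = int(rng.integers(100, 300))
        if ins.codon_bias_shift > 0:
            n_flat = int(round(ins.codon_bias_shift * n_codons))
            body = model.sample(n_codons - n_flat, rng) + flat.sample(n_flat, rng)
        else:
            body = model.sample(n_codons, rng)
        cds = "ATG" + body + codons.STOP_CODONS[int(rng.integers(3))]
        pieces += [spacer, cds]
        total += len(spacer) + len(cds)
    core = "".join(pieces)[: ins.length]
    if ins.flank_style == "direct_repeat":
        rep = random_seq(20, gc, rng)
        return rep + core + rep
    if ins.flank_style == "trna_repeat":
        trnas = reference.features[reference.features.kind == "tRNA"]
        if not len(trnas):
            raise ValueError("trna_repeat insertion requires a tRNA in the reference")
        t = trnas.iloc[int(rng.integers(len(trnas)))]
        rep = reference.seq[t.start:t.end]
        return rep + core + rep
    if ins.flank_style == "same_is":
        template = _is_template(reference, rng)
        return (mutate(template, 0.13, rng) + core + mutate(template, 0.13, rng))
    return core


def _is_template(reference: AnnotatedGenome, rng: np.random.Generator) -> str:
    isf = reference.is_features()
    if len(isf):
        row = isf.iloc[int(rng.integers(len(isf)))]
        return reference.seq[row.start:row.end]
    return random_seq(800, 0.7, rng)


def apply_edits(reference: AnnotatedGenome, plan: EditPlan) -> tuple[str, TruthManifest]:
    """Derive a query genome sequence from the reference and record the truth.

    The query equals the reference with deletions excised and insertions
    spliced in.  The manifest lists every edit, the genes fully or partially
    removed, and the expected query size (reference − deleted + inserted),
    which always equals the actual query length.
    """
    n = len(reference)
    rng = np.random.default_rng(plan.seed)
    genes = reference.gene_features()
    for d in plan.deletions:
        if d.start < 0 or d.end > n:
            raise ValueError(f"deletion [{d.start},{d.end}) outside reference [0,{n})")
    for ins in plan.insertions:
        if not 0 <= ins.anchor <= n:
            raise ValueError(f"insertion anchor {ins.anchor} outside reference")
        inside_gene = ((genes.start < ins.anchor) & (ins.anchor < genes.end)).any()
        if inside_gene:
            raise ValueError(f"insertion anchor {ins.anchor} lies inside a gene")
        if any(d.start < ins.anchor < d.end for d in plan.deletions):
            raise ValueError(f"insertion anchor {ins.anchor} lies inside a deletion")

    events = [(d.start, d.end, "del", d) for d in plan.deletions]
    events += [(i.anchor, i.anchor, "ins", i) for i in plan.insertions]
    events.sort(key=lambda e: (e[0], e[1]))

    pieces, ins_records = [], []
    cursor = qpos = 0
    for start, end, etype, obj in events:
        pieces.append(reference.seq[cursor:start])
        qpos += start - cursor
        if etype == "del":
            cursor = end
        else:
            seq = _foreign_segment(reference, obj, rng)
            pieces.append(seq)
            ins_records.append({"ref_anchor": obj.anchor, "query_start": qpos,
                                "query_end": qpos + len(seq), "length": len(seq),
                                "flank_style": obj.flank_style})
            qpos += len(seq)
            cursor = start
    pieces.append(reference.seq[cursor:])
    query = "".join(pieces)

    fully, partially = set(), set()
    for g in genes.itertuples():
        for d in plan.deletions:
            if d.start <= g.start and g.end <= d.end:
                fully.add(g.feature_id)
                break
            if g.start < d.end and d.start < g.end:
                partially.add(g.feature_id)
    partially -= fully

    total_del = sum(d.end - d.start for d in plan.deletions)
    total_ins = sum(r["length"] for r in ins_records)
    manifest = TruthManifest(
        query_id="query", reference_id=reference.id, reference_size=n,
        expected_size=n - total_del + total_ins,
        fully_deleted=frozenset(fully), partially_deleted=frozenset(partially),
        deletions=plan.deletions, insertions=tuple(ins_records),
        total_deleted_bp=total_del, total_inserted_bp=total_ins)
    assert len(query) == manifest.expected_size
    return query, manifest


# ---------------------------------------------------------------------------
# Flank-element planting (edits the reference around planned deletions)
# ---------------------------------------------------------------------------

def _clean_pos(features: pd.DataFrame, pos: int, direction: int) -> int:
    """Nudge ``pos`` along ``direction`` until it falls between features."""
    for _ in range(64):
        inside = features[(features.start < pos) & (pos < features.end)]
        if not len(inside):
            return pos
        pos = int(inside.iloc[0].start) if direction < 0 else int(inside.iloc[0].end)
    raise RuntimeError("could not find an inter-feature position")


def plant_flank_elements(reference: AnnotatedGenome, deletions: list[Deletion],
                         seed: int = 0) -> tuple[AnnotatedGenome, list[Deletion]]:
    """Splice flanking elements into the reference around planned deletions.

    For each deletion whose ``flank_style`` is not ``none``, an element pair is
    inserted just outside both ends of the interval: an identical ≥15 bp
    sequence (``direct_repeat``), two copies of a reference tRNA gene annotated
    as tRNA features (``trna_repeat``), or two diverged same-family IS copies
    (``same_is``).  Returns the edited genome and the deletions with
    coordinates shifted to the new frame.
    """
    rng = np.random.default_rng(seed)
    feats = reference.features.copy()
    inserts: list[tuple[int, str, list[dict]]] = []  # (pos, seq, feature rows rel to pos)
    counter = 0
    for d in deletions:
        if d.flank_style == "none":
            continue
        counter += 1
        pos_l = _clean_pos(feats, d.start - int(rng.integers(3, 9)), -1)
        pos_r = _clean_pos(feats, d.end + int(rng.integers(3, 9)), +1)
        if d.flank_style == "direct_repeat":
            rep = random_seq(20, 0.7, rng)
            inserts += [(pos_l, rep, []), (pos_r, rep, [])]
        elif d.flank_style == "trna_repeat":
            trnas = feats[feats.kind == "tRNA"]
            if not len(trnas):
                raise ValueError("trna_repeat planting requires a tRNA in the reference")
            t = trnas.iloc[int(rng.integers(len(trnas)))]
            rep = reference.seq[t.start:t.end]
            for side, p in (("a", pos_l), ("b", pos_r)):
                inserts.append((p, rep, [{
                    "feature_id": f"{t.feature_id}cp{counter}{side}", "kind": "tRNA",
                    "start": 0, "end": len(rep), "strand": t.strand,
                    "family": None, "origin": "planted"}]))
        elif d.flank_style == "same_is":
            template = _is_template(reference, rng)
            fam = "ISx"
            isf = reference.is_features()
            if len(isf):
                fam = isf.iloc[0].family
            for side, p in (("a", pos_l), ("b", pos_r)):
                copy = mutate(template, 0.13, rng)
                inserts.append((p, copy, [{
                    "feature_id": f"isP{counter}{side}", "kind": "IS",
                    "start": 0, "end": len(copy), "strand": "+",
                    "family": fam, "origin": "planted"}]))

    seq = reference.seq
    dels = list(deletions)
    new_rows: list[dict] = []
    for pos, ins_seq, rel_rows in sorted(inserts, key=lambda t: -t[0]):
        seq = seq[:pos] + ins_seq + seq[pos:]
        length = len(ins_seq)
        feats.loc[feats.start >= pos, ["start", "end"]] += length
        for row in new_rows:
            if row["start"] >= pos:
                row["start"] += length
                row["end"] += length
        for row in rel_rows:
            new_rows.append({**row, "start": row["start"] + pos, "end": row["end"] + pos})
        dels = [replace(d, start=d.start + length, end=d.end + length)
                if d.start >= pos else d for d in dels]
    if new_rows:
        feats = pd.concat([feats, feature_frame(new_rows)], ignore_index=True)
    feats = feats.sort_values("start", kind="stable").reset_index(drop=True)
    genome = AnnotatedGenome(id=reference.id, seq=seq, features=feats,
                             circular=reference.circular)
    return genome, dels


def design_edit_plan(reference: AnnotatedGenome,
                     cluster_specs: list[tuple[int, str]],
                     n_isolated: int = 0,
                     isolated_flank: str = "none",
                     seed: int = 0) -> EditPlan:
    """Build an EditPlan deleting foreign blocks matching the requested sizes.

    ``cluster_specs`` is a list of (gene count, flank_style); each must match a
    foreign block of exactly that size in the reference.  Isolated deletions
    take single-gene foreign blocks.  Deletion intervals span from the first
    to the last gene of the block, so interior IGRs are removed with the genes
    while the flanking IGRs are retained.
    """
    genes = reference.gene_features().sort_values("start").reset_index(drop=True)
    blocks = []  # (size, first_start, last_end)
    run = []
    for row in genes.itertuples():
        if row.origin == "foreign":
            run.append(row)
        elif run:
            blocks.append(run)
            run = []
    if run:
        blocks.append(run)
    multi = sorted([b for b in blocks if len(b) > 1], key=len)
    single = [b for b in blocks if len(b) == 1]
    deletions = []
    for size, style in cluster_specs:
        match = next((b for b in multi if len(b) == size), None)
        if match is None:
            raise ValueError(f"no unused foreign block of size {size} in reference")
        multi.remove(match)
        deletions.append(Deletion(start=int(match[0].start), end=int(match[-1].end),
                                  kind="clustered", flank_style=style, n_genes=size))
    if n_isolated > len(single):
        raise ValueError(f"only {len(single)} single-gene foreign blocks available")
    for b in single[:n_isolated]:
        deletions.append(Deletion(start=int(b[0].start), end=int(b[0].end),
                                  kind="isolated", flank_style=isolated_flank, n_genes=1))
    return EditPlan(deletions=tuple(deletions), seed=seed)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimSpec:
    """Uniform-depth single-end read simulation parameters."""

    read_len: int = 50
    depth: float = 20.0
    sub_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not 0.0 <= self.sub_error_rate < 1.0:
            raise ValueError("sub_error_rate must be in [0,1)")


@dataclass
class ReadSet:
    """Simulated reads with their provenance (source position and strand)."""

    source_id: str
    read_len: int
    reads: np.ndarray        # (n, read_len) uint8, read orientation
    positions: np.ndarray    # source start on the forward strand
    strands: np.ndarray      # 0 = forward, 1 = reverse

    @property
    def n(self) -> int:
        return self.reads.shape[0]

    def names(self):
        for i in range(self.n):
            yield (f"{self.source_id}.r{i:06d};pos={self.positions[i]};"
                   f"strand={'+-'[self.strands[i]]}")

    def sequences(self):
        for i in range(self.n):
            yield decode(self.reads[i])

    def to_fastq(self, path) -> None:
        qual = "I" * self.read_len
        with open(path, "w") as fh:
            for name, seq in zip(self.names(), self.sequences()):
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def simulate_reads(genome_seq: str, spec: ReadSimSpec, source_id: str = "query") -> ReadSet:
    """Draw uniform-coverage reads from both strands with substitution errors.

    The read count is ``ceil(depth * genome_len / read_len)``; start positions
    are uniform over the forward strand, half the reads are reverse-complement
    sampled, and each base is substituted independently at ``sub_error_rate``.
    """
    n = len(genome_seq)
    if n < spec.read_len:
        raise ValueError(f"genome length {n} shorter than read length {spec.read_len}")
    rng = np.random.default_rng(spec.seed)
    n_reads = math.ceil(spec.depth * n / spec.read_len)
    positions = rng.integers(0, n - spec.read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads).astype(np.uint8)
    codes = encode(genome_seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, spec.read_len)
    reads = windows[positions].copy()
    rev = strands == 1
    rc = reads[rev, ::-1].copy()
    acgt = rc < 4
    rc[acgt] = 3 - rc[acgt]
    reads[rev] = rc
    if spec.sub_error_rate > 0:
        hit = (rng.random(reads.shape) < spec.sub_error_rate) & (reads < 4)
        shift = rng.integers(1, 4, size=reads.shape).astype(np.uint8)
        reads = np.where(hit, (reads + shift) % 4, reads)
    return ReadSet(source_id=source_id, read_len=spec.read_len, reads=reads,
                   positions=positions, strands=strands)
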