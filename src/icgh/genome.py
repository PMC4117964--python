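"""The :class:`AnnotatedGenome` container and its FASTA/GFF3 round trip.

One coordinate frame holds the reference sequence and all typed features.
Internally everything is 0-based half-open; GFF3 (1-based inclusive) is
converted at the boundary.  Feature kinds:

``gene``
    protein-coding gene (creates a gene segment downstream)
``tRNA``
    RNA gene (also a gene segment; gene-total denominators count it)
``IS``
    insertion-sequence element with a ``family`` label (annotation overlay:
    never a segment, consumed only by flank classification)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqs import encode, revcomp

#: feature kinds that become gene segments during dissection
GENE_KINDS = ("gene", "tRNA", "rRNA", "ncRNA")

_GFF_TYPE = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "ncRNA": "ncRNA",
             "IS": "mobile_genetic_element"}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}

FEATURE_COLUMNS = ["feature_id", "kind", "start", "end", "strand", "family", "origin"]


def window_seq(seq: str, circular: bool, start: int, end: int) -> str:
    """Subsequence [start, end) of ``seq``, wrapping the origin if circular,
    clamped to the sequence bounds otherwise."""
    n = len(seq)
    if n == 0 or end <= start:
        return ""
    if circular:
        length = min(end - start, n)
        start %= n
        end = start + length
        if end <= n:
            return seq[start:end]
        return seq[start:] + seq[: end - n]
    return seq[max(0, start) : min(n, end)]


def feature_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return df.astype({"start": np.int64, "end": np.int64})


@dataclass
class AnnotatedGenome:
    """Reference sequence plus typed features in one coordinate frame."""

    id: str
    seq: str
    features: pd.DataFrame
    circular: bool = True
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = set(FEATURE_COLUMNS) - set(self.features.columns)
        if missing:
            raise ValueError(f"features missing columns: {sorted(missing)}")
        bad = self.features[(self.features.start < 0) | (self.features.end > len(self.seq))
                            | (self.features.end <= self.features.start)]
        if len(bad):
            raise ValueError(f"{len(bad)} features outside [0,{len(self.seq)}) or empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None or self._codes.size != len(self.seq):
            object.__setattr__(self, "_codes", encode(self.seq))
        return self._codes

    def gene_features(self) -> pd.DataFrame:
        """Features that define gene segments (protein-coding and RNA genes)."""
        return self.features[self.features.kind.isin(GENE_KINDS)].reset_index(drop=True)

    def is_features(self) -> pd.DataFrame:
        return self.features[self.features.kind == "IS"].reset_index(drop=True)

    def feature_seq(self, feature_id: str) -> str:
        """Strand-aware (coding) sequence of one feature."""
        row = self.features.loc[self.features.feature_id == feature_id]
        if not len(row):
            raise KeyError(feature_id)
        row = row.iloc[0]
        s = self.seq[row.start : row.end]
        return revcomp(s) if row.strand == "-" else s

    def window(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps around the origin when circular."""
        return window_seq(self.seq, self.circular, start, end)

    # ------------------------------------------------------------------ I/O
    def to_fasta(self, path) -> None:
        rec = SeqRecord(Seq(self.seq), id=self.id,
                        description=f"circular={str(self.circular).lower()}")
        SeqIO.write([rec], str(path), "fasta")

    def to_gff3(self, path) -> None:
        lines = ["##gff-version 3", f"##sequence-region {self.id} 1 {len(self.seq)}"]
        for row in self.features.itertuples():
            attrs = [f"ID={row.feature_id}"]
            if isinstance(row.family, str) and row.family:
                attrs.append(f"family={row.family}")
            if isinstance(row.origin, str) and row.origin:
                attrs.append(f"origin={row.origin}")
            lines.append("\t".join([
                self.id, "icgh", _GFF_TYPE[row.kind], str(row.start + 1),
                str(row.end), ".", row.strand, ".", ";".join(attrs),
            ]))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def read_genome(fasta_path, gff3_path, *, circular: bool | None = None) -> AnnotatedGenome:
    """Load an annotated genome from FASTA + GFF3."""
    import gffutils

    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    if circular is None:
        circular = "circular=true" in rec.description.lower()
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.all_features(order_by=("start",)):
        kind = _GFF_TYPE_REV.get(feat.featuretype)
        if kind is None:
            continue
        rows.append({
            "feature_id": feat.attributes.get("ID", [feat.id])[0],
            "kind": kind,
            "start": feat.start - 1,
            "end": feat.end,
            "strand": feat.strand if feat.strand in "+-" else "+",
            "family": feat.attributes.get("family", [None])[0],
            "origin": feat.attributes.get("origin", [None])[0],
        })
    return AnnotatedGenome(id=rec.id, seq=str(rec.seq).upper(),
                           features=feature_frame(rows), circular=circular)
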