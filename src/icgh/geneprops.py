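"""GC3 and codon adaptation index (CAI) per protein-coding gene.

GC3 is the percentage of G or C at third codon positions, excluding the
terminal stop codon and skipping ambiguous third positions.  CAI is the
geometric mean of per-codon relative adaptedness *w* against a highly
expressed reference gene set (Sharp & Li's construction): within each
synonymous family, w(codon) = count(codon) / count(most frequent codon);
Met, Trp and stop codons carry no information and are excluded from the
product.  Both statistics are computed strictly on the annotated coding
strand, under the bacterial translation table (11).

Genes absent from a query (LCR genes) that arrived by horizontal transfer
are expected to show lower GC3 and CAI than the genome background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import AA_TO_CODONS, CODON_TO_AA, SENSE_CODONS, SINGLE_CODON_AAS, split_codons
from .genome import AnnotatedGenome

__all__ = ["CodonWeights", "gc3", "codon_weights", "cai",
           "gene_property_table", "group_contrast"]

_UNAMBIGUOUS = set("ACGT")


def gc3(cds: str) -> float:
    """GC percentage at third codon positions of a coding sequence.

    The terminal stop codon is excluded; codons whose third base is ambiguous
    are skipped from numerator and denominator.  Raises if the length is not
    a multiple of three or no third position is countable.
    """
    thirds = [c[2] for c in split_codons(cds)]
    counted = [t for t in thirds if t in _UNAMBIGUOUS]
    if not counted:
        raise ValueError("no unambiguous third codon positions")
    return 100.0 * sum(t in "GC" for t in counted) / len(counted)


@dataclass(frozen=True)
class CodonWeights:
    """Relative adaptedness per sense codon, from a reference gene set."""

    w: dict[str, float]
    reference_set_ids: tuple[str, ...] = ()

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, CODON_TO_AA[c], self.w[c]) for c in SENSE_CODONS]
        return pd.DataFrame(rows, columns=["codon", "amino_acid", "w"])


def codon_weights(reference_cds: dict[str, str] | list[str]) -> CodonWeights:
    """Relative adaptedness from a (highly expressed) reference gene set.

    Zero-count codons are floored at w = 0.01 to keep the geometric mean
    finite; a family with no observed codon at all is uninformative and gets
    w = 1 throughout.
    """
    if isinstance(reference_cds, dict):
        ids, seqs = tuple(reference_cds), list(reference_cds.values())
    else:
        ids, seqs = (), list(reference_cds)
    if not seqs:
        raise ValueError("reference gene set is empty")
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for cds in seqs:
        for codon in split_codons(cds):
            if codon in counts:
                counts[codon] += 1
    w = {}
    for aa, fam in AA_TO_CODONS.items():
        top = max(counts[c] for c in fam)
        for c in fam:
            w[c] = max(counts[c] / top, 0.01) if top > 0 else 1.0
    return CodonWeights(w=w, reference_set_ids=ids)


def cai(cds: str, weights: CodonWeights) -> float:
    """Codon adaptation index: geometric mean of w over countable codons.

    Codons for Met and Trp (no synonymous choice), stop codons and codons
    with ambiguous bases are not counted.  Raises if nothing is countable.
    """
    logs = []
    for codon in split_codons(cds):
        aa = CODON_TO_AA.get(codon)
        if aa is None or aa in SINGLE_CODON_AAS:
            continue
        logs.append(np.log(weights[codon]))
    if not logs:
        raise ValueError("no countable codons for CAI")
    return float(np.exp(np.mean(logs)))


def gene_property_table(genome: AnnotatedGenome, weights: CodonWeights,
                        lcr_nonredundant: set[str] = frozenset()) -> pd.DataFrame:
    """GC3 and CAI for every protein-coding gene, with its membership in the
    nonredundant LCR union."""
    rows = []
    for g in genome.features[genome.features.kind == "gene"].itertuples():
        cds = genome.feature_seq(g.feature_id)
        rows.append((g.feature_id, gc3(cds), cai(cds, weights),
                     g.feature_id in lcr_nonredundant))
    return pd.DataFrame(rows, columns=["gene_id", "gc3", "cai", "lcr_nonredundant"])


def group_contrast(records: pd.DataFrame,
                   flag_col: str = "lcr_nonredundant") -> pd.DataFrame:
    """Mean GC3 and CAI for the flagged group vs all other genes."""
    flagged = records[records[flag_col]]
    other = records[~records[flag_col]]
    if not len(flagged) or not len(other):
        raise ValueError("both groups must be non-empty")
    return pd.DataFrame({
        "group": ["lcr_nonredundant", "other"],
        "n": [len(flagged), len(other)],
        "mean_gc3": [flagged.gc3.mean(), other.gc3.mean()],
        "mean_cai": [flagged.cai.mean(), other.cai.mean()],
    })
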