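"""Codon table 11 bookkeeping and parametric codon-usage models.

The bacterial/archaeal translation table (NCBI table 11) is taken from
Biopython.  Usage models are simple per-amino-acid categorical distributions
parameterised by a target GC fraction at the third codon position, which is
the knob the synthetic generator turns to emulate native, highly expressed and
foreign (horizontally acquired) coding sequence.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

TABLE = CodonTable.unambiguous_dna_by_id[11]

STOP_CODONS: tuple[str, ...] = tuple(sorted(TABLE.stop_codons))
CODON_TO_AA: dict[str, str] = dict(TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: Amino acids excluded from CAI products: no synonymous choice exists.
SINGLE_CODON_AAS = frozenset(aa for aa, cs in AA_TO_CODONS.items() if len(cs) == 1)


class CodonUsageModel:
    """Categorical distribution over the 61 sense codons.

    Parameters
    ----------
    gc3:
        Target probability that a sampled codon ends in G or C, applied
        within each synonymous family that offers the choice.
    concentration:
        If given, each family's probability mass is shifted onto its single
        preferred codon (the highest-probability codon of the plain model,
        ties broken lexicographically) with this weight; the remainder is
        spread uniformly over the other synonymous codons.  Models the sharp
        bias of highly expressed genes.
    """

    def __init__(self, gc3: float = 0.5, concentration: float | None = None):
        if not 0.0 < gc3 < 1.0:
            raise ValueError(f"gc3 must be in (0,1), got {gc3}")
        self.gc3 = gc3
        self.concentration = concentration
        probs = {}
        for aa, codons in AA_TO_CODONS.items():
            w = np.array([gc3 if c[2] in "GC" else 1.0 - gc3 for c in codons])
            w = w / w.sum()
            if concentration is not None and len(codons) > 1:
                pref = int(np.argmax(w))  # first max: lexicographic tie-break
                w = np.full(len(codons), (1.0 - concentration) / (len(codons) - 1))
                w[pref] = concentration
            for c, p in zip(codons, w):
                probs[c] = p / len(AA_TO_CODONS)  # uniform amino-acid usage
        self._codons = np.array(SENSE_CODONS)
        self._p = np.array([probs[c] for c in SENSE_CODONS])
        self._p = self._p / self._p.sum()

    def sample(self, n: int, rng: np.random.Generator) -> str:
        """Sample ``n`` sense codons as a concatenated string."""
        idx = rng.choice(self._codons.size, size=n, p=self._p)
        return "".join(self._codons[idx])


@lru_cache(maxsize=32)
def usage_model(gc3: float, concentration: float | None = None) -> CodonUsageModel:
    return CodonUsageModel(gc3=gc3, concentration=concentration)


def split_codons(cds: str, *, drop_terminal_stop: bool = True) -> list[str]:
    """Split a CDS into codons, optionally dropping a terminal stop codon.

    Raises ``ValueError`` if the length is not a multiple of three.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if drop_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons.pop()
    return codons
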