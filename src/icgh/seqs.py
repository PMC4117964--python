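"""Low-level nucleotide utilities shared across the package.

Sequences are plain Python strings over {A,C,G,T,N} in user-facing APIs and
uint8 arrays (A=0, C=1, G=2, T=3, anything else=4) in numeric kernels.  Code 4
never matches any base, which is how ambiguous/masked positions are excluded
from alignment and mapping.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENC = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0..T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[np.minimum(codes, N_CODE)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < N_CODE
    out[acgt] = 3 - out[acgt]
    return out


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with the given expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply substitutions at the given per-base rate (to a different base)."""
    codes = encode(seq).copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return decode(codes)
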