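"""Low-level DNA sequence helpers shared across the package.

Sequences are handled either as uppercase python strings over {A,C,G,T,N}
or, for heavy numerical work, as ``numpy.uint8`` code arrays with
A=0, C=1, G=2, T=3, N=4.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (case-insensitive)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"invalid DNA character {seq[bad]!r} at position {bad}")
    return codes.copy()


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def cpg_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of positions participating in a CG dinucleotide."""
    mask = np.zeros(codes.shape, dtype=bool)
    if codes.size >= 2:
        pair = (codes[:-1] == C) & (codes[1:] == G)
        mask[:-1] |= pair
        mask[1:] |= pair
    return mask


def cpg_sites(seq: str) -> np.ndarray:
    return cpg_mask(encode(seq))


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, length, dtype=np.uint8))
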