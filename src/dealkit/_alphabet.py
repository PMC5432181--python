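"""Nucleotide alphabet utilities.

Sequences are manipulated in two representations: plain strings over the
IUPAC alphabet for I/O, and numpy ``uint8`` bit-mask arrays for the inner
clustering loops.  Each of A/C/G/T occupies one bit, so an IUPAC ambiguity
code is exactly the bitwise OR of the bases it stands for — merging two
uncertain calls is a single vectorised ``|``.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import reverse_complement as _bio_revcomp

# bit assignment: A=1, C=2, G=4, T=8
CODE_TO_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 1 | 2, "R": 1 | 4, "W": 1 | 8, "S": 2 | 4, "Y": 2 | 8, "K": 4 | 8,
    "V": 1 | 2 | 4, "H": 1 | 2 | 8, "D": 1 | 4 | 8, "B": 2 | 4 | 8,
    "N": 15,
}
MASK_TO_CODE: dict[int, str] = {m: c for c, m in CODE_TO_MASK.items()}

_ENCODE = np.zeros(256, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    _ENCODE[ord(_c)] = _m
    _ENCODE[ord(_c.lower())] = _m

_DECODE = np.zeros(16, dtype=np.uint8)
for _m, _c in MASK_TO_CODE.items():
    _DECODE[_m] = ord(_c)

# complement swaps A<->T and C<->G, i.e. reverses the 4-bit pattern
_COMPLEMENT = np.zeros(16, dtype=np.uint8)
for _m in range(16):
    _r = ((_m & 1) << 3) | ((_m & 2) << 1) | ((_m & 4) >> 1) | ((_m & 8) >> 3)
    _COMPLEMENT[_m] = _r

#: masks holding exactly one base (reliable, concrete calls)
_POPCOUNT = np.array([bin(m).count("1") for m in range(16)], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC nucleotide string as a uint8 bit-mask array."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    masks = _ENCODE[raw]
    if masks.size and not masks.all():
        bad = chr(raw[int(np.argmin(masks != 0))])
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return masks


def decode(masks: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[masks].tobytes().decode("ascii")


def complement_masks(masks: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[masks]


def is_concrete(masks: np.ndarray) -> np.ndarray:
    """True where the mask holds a single unambiguous base."""
    return _POPCOUNT[masks] == 1


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return _bio_revcomp(seq)
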