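"""Shared sequence utilities: base encoding, complements, FASTA/FASTQ helpers.

Bases are encoded A=0, C=1, G=2, T=3 so that complementation is ``3 - code``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (255 for N/other)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 base codes back into a DNA string (255 -> N)."""
    out = np.where(codes < 4, _DECODE[np.minimum(codes, 3)], ord("N"))
    return out.astype(np.uint8).tobytes().decode()


def complement_code(codes: np.ndarray) -> np.ndarray:
    """Complement encoded bases; non-ACGT codes are left untouched."""
    out = np.where(codes < 4, 3 - codes, codes)
    return out.astype(np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
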