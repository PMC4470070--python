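"""Small sequence utilities shared by the simulator and the aligner.

Sequences are held internally as ``numpy.uint8`` code arrays (0..3 for
A, C, G, T) so that mutation, digestion and k-mer packing stay vectorised;
they are decoded to strings only at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

ALPHABET = b"ACGT"
_DECODE = np.frombuffer(ALPHABET, dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[_c] = _i
    _ENCODE[_c + 32] = _i  # lower case

# complement of code i is 3 - i under the A,C,G,T ordering
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an A/C/G/T string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode()
    raw = np.frombuffer(seq, dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an A/C/G/T string."""
    return _DECODE[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array."""
    return COMPLEMENT[codes[::-1]]


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    """i.i.d. random sequence with the given GC fraction."""
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def sequence_identity(a: np.ndarray | str, b: np.ndarray | str) -> float:
    """Global pairwise identity, 1 - edit_distance / max(len).

    Uses edlib's Needleman-Wunsch edit distance; for equal-length
    substitution-only pairs this reduces to the exact match fraction.
    """
    import edlib

    sa = decode(a) if isinstance(a, np.ndarray) else a
    sb = decode(b) if isinstance(b, np.ndarray) else b
    if not sa or not sb:
        raise ValueError("identity of empty sequence is undefined")
    d = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(sa), len(sb))
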