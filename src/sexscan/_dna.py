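"""Low-level DNA utilities: 2-bit encoding, canonical k-mer extraction.

k-mers up to k=32 are packed into uint64 (2 bits per base, A=0 C=1 G=2 T=3,
most significant bits = 5' end).  The canonical form of a k-mer is the
lexicographic minimum of the k-mer and its reverse complement, which under
this encoding equals the numeric minimum of the two packed values.
"""

from __future__ import annotations

import numpy as np

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    raw = np.frombuffer(seq, dtype=np.uint8)
    return _CODES[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid (0..3) codes."""
    return _BASES[codes].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int, canonical: bool = True) -> np.ndarray:
    """Packed k-mer codes at every valid position of an encoded sequence.

    Positions whose window overlaps a non-ACGT base are dropped.  With
    ``canonical=True`` each k-mer is replaced by min(kmer, revcomp(kmer)).
    """
    if not 1 <= k <= 32:
        raise ValueError("k must be in 1..32")
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        cj = codes[j : j + m]
        bad |= cj == 255
        fwd = (fwd << np.uint64(2)) | (cj & np.uint8(3)).astype(np.uint64)
        cr = codes[k - 1 - j : k - 1 - j + m]
        rev = (rev << np.uint64(2)) | ((3 - cr) & np.uint8(3)).astype(np.uint64)
    out = np.minimum(fwd, rev) if canonical else fwd
    if bad.any():
        out = out[~bad]
    return out


def kmer_positions(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`kmer_codes` (canonical) but also return 0-based positions."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        cj = codes[j : j + m]
        bad |= cj == 255
        fwd = (fwd << np.uint64(2)) | (cj & np.uint8(3)).astype(np.uint64)
        cr = codes[k - 1 - j : k - 1 - j + m]
        rev = (rev << np.uint64(2)) | ((3 - cr) & np.uint8(3)).astype(np.uint64)
    canon = np.minimum(fwd, rev)
    pos = np.arange(m, dtype=np.int64)
    if bad.any():
        canon, pos = canon[~bad], pos[~bad]
    return canon, pos


def pack_kmer(kmer: str) -> int:
    """Pack a k-mer string into its uint64 code (non-canonical)."""
    codes = encode(kmer)
    if (codes == 255).any():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def unpack_kmer(code: int, k: int) -> str:
    """Inverse of :func:`pack_kmer`."""
    out = bytearray(k)
    for j in range(k - 1, -1, -1):
        out[j] = _BASES[code & 3]
        code >>= 2
    return out.decode("ascii")


def canonical(kmer: str) -> str:
    """Canonical (lexicographically minimal) form of a k-mer string."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))
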