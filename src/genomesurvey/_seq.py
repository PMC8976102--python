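"""Low-level nucleotide sequence utilities shared across the package.

Sequences are held internally as ``numpy.uint8`` arrays with the 2-bit
encoding A=0, C=1, G=2, T=3 (255 marks any non-ACGT symbol).  K-mers with
k <= 31 are packed into ``uint64`` codes, two bits per base, which makes
canonicalization and counting fully vectorizable.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array (255 = non-ACGT)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an uppercase string."""
    if codes.size and codes.max() > 3:
        out = np.full(codes.shape, ord("N"), dtype=np.uint8)
        ok = codes <= 3
        out[ok] = _DECODE[codes[ok]]
        return out.tobytes().decode("ascii")
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement of a base-code array."""
    out = codes[::-1].copy()
    ok = out <= 3
    out[ok] = 3 - out[ok]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def gc_fraction(codes: np.ndarray) -> float:
    """Fraction of G+C among ACGT bases."""
    ok = codes <= 3
    n = int(ok.sum())
    if n == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n


def kmer_codes_1d(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-window of a 1-D code array into uint64 k-mer codes.

    Returns ``(kcodes, valid)`` where ``valid`` flags windows free of
    non-ACGT symbols.  Requires ``k <= 31``.
    """
    if k > 31:
        raise ValueError("packed k-mer codes require k <= 31")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = codes > 3
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
        valid = (cs[k:] - cs[:-k]) == 0
        codes = np.where(bad, 0, codes)
    else:
        valid = np.ones(n, dtype=bool)
    acc = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    for j in range(k):
        acc *= four
        acc += codes[j : j + n].astype(np.uint64)
    return acc, valid


def kmer_codes_2d(mat: np.ndarray, k: int) -> np.ndarray:
    """Pack k-windows of each row of a (reads x length) code matrix.

    Assumes all entries are valid ACGT codes (the simulator guarantees it).
    Returns an (reads x (length-k+1)) uint64 array.
    """
    if k > 31:
        raise ValueError("packed k-mer codes require k <= 31")
    nwin = mat.shape[1] - k + 1
    if nwin <= 0:
        return np.empty((mat.shape[0], 0), dtype=np.uint64)
    acc = np.zeros((mat.shape[0], nwin), dtype=np.uint64)
    four = np.uint64(4)
    for j in range(k):
        acc *= four
        acc += mat[:, j : j + nwin].astype(np.uint64)
    return acc


def revcomp_kmer_codes(kcodes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed uint64 k-mer codes."""
    x = (~kcodes).astype(np.uint64)
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_kmer_codes(kcodes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic minimum of each packed k-mer and its reverse complement."""
    return np.minimum(kcodes, revcomp_kmer_codes(kcodes, k))


def kmer_code_to_str(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))
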