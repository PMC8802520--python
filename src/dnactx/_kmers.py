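"""Integer encodings for DNA k-mers.

Bases are coded A=0, C=1, G=2, T=3, N=4, so complementation is ``3 - code``
for proper bases. A k-mer is packed into a single int64 in base 4 with the
5'-most base in the most significant digit; int64 holds k-mers up to k=31,
far beyond any order used here.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (anything non-ACGT -> N)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement, keeping N fixed."""
    out = 3 - codes
    if np.ndim(codes):
        out = np.where(codes == N_CODE, N_CODE, out)
    elif codes == N_CODE:
        out = N_CODE
    return out.astype(np.uint8) if np.ndim(codes) else np.uint8(out)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return complement_codes(codes)[::-1]


def kmer_to_int(codes: np.ndarray) -> int:
    """Pack an N-free k-mer code array into an int (big-endian base 4)."""
    val = 0
    for c in codes:
        if c >= 4:
            raise ValueError("k-mer contains N")
        val = val * 4 + int(c)
    return val


def int_to_kmer(val: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[val % 4])
        val //= 4
    return "".join(reversed(out))


def revcomp_int(codes: np.ndarray | int, k: int) -> np.ndarray | int:
    """Reverse-complement packed k-mer code(s) of length k."""
    c = np.asarray(codes, dtype=np.int64).copy()
    out = np.zeros_like(c)
    for _ in range(k):
        out = out * 4 + (3 - (c % 4))
        c //= 4
    return out if isinstance(codes, np.ndarray) else int(out)


def window_codes(codes: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes and N-free validity for every length-m window.

    Returns (window_code[int64], valid[bool]) both of length len(codes)-m+1;
    windows containing N get an arbitrary code and valid=False.
    """
    n = len(codes) - m + 1
    if n <= 0:
        return np.zeros(0, np.int64), np.zeros(0, bool)
    is_n = codes == N_CODE
    cs = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cs[m:] - cs[:-m]) == 0
    x = np.where(is_n, 0, codes).astype(np.int64)
    w = np.zeros(n, np.int64)
    for j in range(m):
        w = w * 4 + x[j : j + n]
    return w, valid
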