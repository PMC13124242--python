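"""2-bit k-mer codecs.

A k-mer over {A,C,G,T} with k <= 31 packs into one uint64, first base in the
most significant bits, so unsigned integer comparison equals lexicographic
string comparison (A<C<G<T). The canonical form of a k-mer is the smaller of
the k-mer and its reverse complement; for odd k the two are never equal.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a sequence to per-base codes (A=0,C=1,G=2,T=3; other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean array: window i (of L-k+1) contains only A/C/G/T."""
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    return (cum[k:] - cum[:-k]) == 0


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward, reverse-complement, and validity arrays for all k windows.

    Invalid (non-ACGT) bases contribute 0 bits; consult the validity mask
    before using a window's code.
    """
    n = codes.shape[0]
    m = n - k + 1
    if m <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=bool)
    safe = np.where(codes < 4, codes, 0).astype(np.uint64)
    comp = (3 - safe) & np.uint64(3)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + m]
        rev = (rev << np.uint64(2)) | comp[k - 1 - j : k - 1 - j + m]
    return fwd, rev, window_valid(codes, k)


def encode_kmer(kmer: str) -> int | None:
    """Pack one k-mer; None if it contains non-ACGT characters."""
    codes = seq_to_codes(kmer)
    if (codes >= 4).any():
        return None
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc
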