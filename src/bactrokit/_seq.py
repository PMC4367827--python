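"""Low-level sequence utilities shared across the package.

Sequences are plain uppercase ``str`` over {A,C,G,T,N} at the API surface;
hot loops convert to 2-bit integer codes via numpy.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte value -> 2-bit code; N and anything else -> 4 (sentinel)
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit encode a DNA string; non-ACGT bases become the sentinel 4."""
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | _BASES.index(ch)
    return code


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes of a 2-bit code array.

    Windows containing the sentinel (N) are dropped.  Returns an int64
    array of length ``len(codes) - k + 1`` minus dropped windows.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = codes.astype(np.int64)
    roll = np.zeros(n, dtype=np.int64)
    for j in range(k):
        roll = (roll << 2) | (vals[j : j + n] & 3)
    if (codes == 4).any():
        bad = (codes == 4).astype(np.int32)
        # window contains an N iff the cumulative N-count changes across it
        cs = np.concatenate(([0], np.cumsum(bad)))
        keep = (cs[k:] - cs[:-k]) == 0
        roll = roll[keep]
    return roll


def kmer_codes_with_pos(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`kmer_codes` but also returns the start position of each
    retained (N-free) window."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = codes.astype(np.int64)
    roll = np.zeros(n, dtype=np.int64)
    for j in range(k):
        roll = (roll << 2) | (vals[j : j + n] & 3)
    pos = np.arange(n, dtype=np.int64)
    if (codes == 4).any():
        bad = (codes == 4).astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(bad)))
        keep = (cs[k:] - cs[:-k]) == 0
        roll, pos = roll[keep], pos[keep]
    return roll, pos


def revcomp_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def min_rotation(seq: str) -> str:
    """Lexicographically minimal rotation (Booth-style via doubling)."""
    if not seq:
        return seq
    doubled = seq + seq
    best = min(doubled[i : i + len(seq)] for i in range(len(seq)))
    return best


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def mismatch_count(ref_codes: np.ndarray, start: int, read_codes: np.ndarray) -> int:
    """Mismatches of a read laid on ref at ``start`` (no gaps)."""
    seg = ref_codes[start : start + read_codes.size]
    if seg.size != read_codes.size:
        return read_codes.size
    return int(np.count_nonzero(seg != read_codes))


def substitution_neighbors(kmer: str) -> list[str]:
    """All 3k single-substitution neighbours (the k-mer itself excluded)."""
    out = []
    for i, ch in enumerate(kmer):
        for b in _BASES:
            if b != ch:
                out.append(kmer[:i] + b + kmer[i + 1 :])
    return out


def deletion_neighbors(kmer: str) -> list[str]:
    """Distinct strings from deleting one base (length k-1)."""
    return sorted({kmer[:i] + kmer[i + 1 :] for i in range(len(kmer))})


def insertion_neighbors(kmer: str) -> list[str]:
    """Distinct strings from inserting one base (length k+1)."""
    out = set()
    for i in range(len(kmer) + 1):
        for b in _BASES:
            out.add(kmer[:i] + b + kmer[i:])
    return sorted(out)
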