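"""Canonical k-mer counting on 2-bit encoded integers.

Every k-mer (k odd, k <= 31) is packed into a uint64, two bits per base
(A=0, C=1, G=2, T=3), and stored in canonical form: the lexicographic
minimum of the k-mer and its reverse complement. Odd k guarantees no
k-mer is its own reverse complement, so canonicalization has no ties.
Windows containing any non-ACGT character are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_U2 = np.uint64(2)
_U3 = np.uint64(3)

# ASCII -> 2-bit base code; -1 marks non-ACGT
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _check_k(k: int) -> None:
    if not (1 <= k <= 31):
        raise ValueError(f"k must be in [1, 31], got {k}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd to avoid palindromic k-mers, got {k}")


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes, vectorized."""
    rc = np.zeros_like(codes, dtype=np.uint64)
    x = codes.astype(np.uint64, copy=True)
    for _ in range(k):
        rc = (rc << _U2) | (_U3 - (x & _U3))
        x >>= _U2
    return rc


def canonicalize(codes: np.ndarray, k: int) -> np.ndarray:
    """Map each packed k-mer to min(kmer, revcomp(kmer))."""
    return np.minimum(codes, revcomp_codes(codes, k))


def encode_kmers(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """All k-mer codes of ``seq`` in order; windows with non-ACGT skipped.

    Returns an empty array when the sequence is shorter than k.
    """
    _check_k(k)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = raw.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    codes = _CODE[raw]
    bad = codes < 0
    base = np.where(bad, 0, codes).astype(np.uint64)
    m = n - k + 1
    packed = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        packed = (packed << _U2) | base[i : i + m]
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        packed = packed[(cs[k:] - cs[:-k]) == 0]
    return canonicalize(packed, k) if canonical else packed


def encode_string(kmer: str) -> int:
    """Pack a single k-mer string (non-canonical)."""
    code = 0
    for ch in kmer.upper():
        b = _CODE[ord(ch)]
        if b < 0:
            raise ValueError(f"non-ACGT character in k-mer: {kmer!r}")
        code = (code << 2) | int(b)
    return code


def decode(code: int, k: int) -> str:
    """Unpack a k-mer code back to an uppercase ACGT string."""
    out = bytearray(k)
    c = int(code)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[c & 3]
        c >>= 2
    return out.decode("ascii")


def decode_many(codes: np.ndarray, k: int) -> list[str]:
    return [decode(c, k) for c in codes]


@dataclass
class KmerCountTable:
    """Counts of canonical k-mers, keyed by sorted unique packed codes.

    Parameters
    ----------
    k
        k-mer size (odd, <= 31).
    codes
        Sorted unique uint64 canonical codes.
    counts
        Per-code counts, all >= 1.
    source
        Free-text provenance tag, e.g. ``assembly``, ``reads_M``, ``reads_F``.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        _check_k(self.k)
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must have equal length")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("all k-mer counts must be >= 1")

    def __len__(self) -> int:
        return self.codes.size

    @classmethod
    def from_code_multiset(cls, codes: np.ndarray, k: int, source: str = "") -> "KmerCountTable":
        """Aggregate a (possibly repeated) stream of canonical codes."""
        uniq, counts = np.unique(np.asarray(codes, dtype=np.uint64), return_counts=True)
        return cls(k=k, codes=uniq, counts=counts, source=source)

    @classmethod
    def from_sequences(cls, seqs, k: int, source: str = "") -> "KmerCountTable":
        parts = [encode_kmers(s, k) for s in seqs]
        allcodes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
        return cls.from_code_multiset(allcodes, k, source=source)

    def get(self, kmer: str) -> int:
        """Count of one k-mer (queried in either strand orientation)."""
        code = canonicalize(np.array([encode_string(kmer)], dtype=np.uint64), self.k)[0]
        idx = np.searchsorted(self.codes, code)
        if idx < self.codes.size and self.codes[idx] == code:
            return int(self.counts[idx])
        return 0

    def filter_min_count(self, min_count: int) -> np.ndarray:
        """Sorted codes whose count is >= ``min_count``."""
        return self.codes[self.counts >= min_count]

    def to_frame(self) -> pd.DataFrame:
        """Table with k-mers as uppercase strings, sorted by code."""
        return pd.DataFrame(
            {"kmer": decode_many(self.codes, self.k), "count": self.counts}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: int, source: str = "") -> "KmerCountTable":
        codes = canonicalize(
            np.array([encode_string(s) for s in df["kmer"]], dtype=np.uint64), k
        )
        order = np.argsort(codes, kind="stable")
        return cls(k=k, codes=codes[order], counts=df["count"].to_numpy()[order], source=source)
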