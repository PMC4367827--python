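"""Exact k-mer counting over read sets and the k-mer histogram genome-size
estimator.

Counting is exact (every N-free window of every read contributes) and
vectorised: reads are 2-bit packed and rolled into int64 codes, so k is
limited to 31.  Two strand policies exist: "as-read" keeps a k-mer and its
reverse complement as distinct keys (required by the strand-directional
extension walk and the satellite spacing statistics) and "canonical" merges
them under the lexicographically smaller key (used for genome-size work,
where reads come off both strands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import decode_kmer, encode, encode_kmer, kmer_codes

_BATCH_READS = 4000


class CoverageTooLow(ValueError):
    """No k-mer multiplicity peak beyond the error trough."""


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


@dataclass
class KmerTable:
    """Exact k-mer counts.  ``codes``/``counts`` are parallel arrays sorted
    by code; ``lookup`` maps code -> count for O(1) single queries."""

    k: int
    strand_policy: str
    codes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lookup: dict[int, int] = dict(
            zip(self.codes.tolist(), self.counts.tolist())
        )

    def get(self, kmer: str) -> int:
        return self.lookup.get(encode_kmer(kmer), 0)

    def get_code(self, code: int) -> int:
        return self.lookup.get(code, 0)

    def __len__(self) -> int:
        return self.codes.size

    def total_kmers(self) -> int:
        return int(self.counts.sum())

    def most_common(self, n: int) -> list[tuple[int, int]]:
        """Top-n (code, count), descending count, lexicographic tie-break."""
        order = np.lexsort((self.codes, -self.counts.astype(np.int64)))[:n]
        return [(int(self.codes[i]), int(self.counts[i])) for i in order]

    def as_dict(self) -> dict[str, int]:
        """String-keyed counts; intended for small tables and tests."""
        return {decode_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}

    def histogram(self) -> "KmerHistogram":
        mult = np.bincount(self.counts.astype(np.int64))
        return KmerHistogram(spectrum=mult)


def count_kmers(reads, k: int, strand_policy: str = "canonical") -> KmerTable:
    """Count every N-free k-mer window of every read.

    ``reads`` may be a ReadSet, an iterable of (id, seq) pairs, a list of
    sequences, or a single sequence string.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > 31:
        raise ValueError("k is limited to 31 (64-bit packing)")
    if strand_policy not in ("as-read", "canonical"):
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    if isinstance(reads, str):
        seqs = [reads]
    elif hasattr(reads, "seqs"):
        seqs = reads.seqs
    else:
        seqs = [r[1] if isinstance(r, tuple) else r for r in reads]

    chunks: list[np.ndarray] = []
    sep = "N" * 1  # one N suffices to break windows between reads
    for i in range(0, len(seqs), _BATCH_READS):
        batch = sep.join(seqs[i : i + _BATCH_READS])
        codes = kmer_codes(encode(batch), k)
        chunks.append(codes)
    if chunks:
        allc = np.concatenate(chunks)
    else:
        allc = np.empty(0, dtype=np.int64)
    if strand_policy == "canonical" and allc.size:
        allc = np.minimum(allc, _revcomp_codes(allc, k))
    uniq, counts = np.unique(allc, return_counts=True)
    return KmerTable(k=k, strand_policy=strand_policy, codes=uniq, counts=counts)


@dataclass
class KmerHistogram:
    """``spectrum[m]`` = number of distinct k-mers seen m times."""

    spectrum: np.ndarray

    def n_distinct(self) -> int:
        return int(self.spectrum[1:].sum())

    def total_kmers(self) -> int:
        return int((self.spectrum * np.arange(self.spectrum.size)).sum())

    def peaks(self) -> tuple[int, int]:
        """(error trough multiplicity, main peak multiplicity).

        The trough is the first multiplicity where the raw spectrum starts
        rising; the main peak is the argmax beyond it of the window-3
        median-smoothed spectrum (falling back to the raw spectrum when
        smoothing flattens a sharp peak away).
        """
        from scipy.signal import medfilt

        s = self.spectrum.astype(float)
        if s.size < 4:
            raise CoverageTooLow("k-mer spectrum too short to find a peak")
        trough = None
        for m in range(1, s.size - 1):
            if s[m + 1] > s[m]:
                trough = m
                break
        if trough is None:
            raise CoverageTooLow("coverage too low: no multiplicity peak beyond trough")
        sm = medfilt(s, kernel_size=3)
        peak = trough + 1 + int(np.argmax(sm[trough + 1 :]))
        if sm[peak] <= 0:
            peak = trough + 1 + int(np.argmax(s[trough + 1 :]))
        if s[peak] <= 0 or peak <= trough:
            raise CoverageTooLow("coverage too low: no multiplicity peak beyond trough")
        return trough, peak

    def refined_peak(self) -> float:
        """Sub-integer peak multiplicity: centroid of the raw spectrum over
        a +-sqrt(peak) window (the histogram mode alone is too coarse and
        sits below the mean of the Poisson-like single-copy peak)."""
        trough, peak = self.peaks()
        c = float(peak)
        mult = np.arange(self.spectrum.size)
        for _ in range(3):  # recenter the band on the current estimate
            lo = max(trough + 1, int(round(0.5 * c)))
            hi = min(self.spectrum.size, int(round(1.5 * c)) + 1)
            w = self.spectrum[lo:hi].astype(float)
            if w.sum() == 0:
                break
            c = float((mult[lo:hi] * w).sum() / w.sum())
        return c

    def solid_total(self) -> int:
        """Total k-mer occurrences above the error trough."""
        trough, _ = self.peaks()
        m = np.arange(self.spectrum.size)
        keep = m > trough
        return int((self.spectrum[keep] * m[keep]).sum())


def genome_size_from_histogram(hist: KmerHistogram, total_kmers: int | None = None) -> float:
    """Haploid genome size in bp: total k-mers / main-peak multiplicity.

    When ``total_kmers`` is not given, occurrences at or below the error
    trough are excluded from the total (sequencing-error k-mers would
    otherwise inflate the numerator) and the centroid-refined peak is used.
    """
    if total_kmers is None:
        return hist.solid_total() / hist.refined_peak()
    return total_kmers / hist.refined_peak()


def genome_size_from_reads(reads, k: int = 18) -> float:
    """Convenience: canonical k-mer counting then the histogram estimator."""
    table = count_kmers(reads, k, strand_policy="canonical")
    return genome_size_from_histogram(table.histogram())
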