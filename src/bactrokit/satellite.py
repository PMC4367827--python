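"""Satellite arrangement and abundance statistics computed from raw reads.

A satellite monomer of length L (100-300 bp) is longer than a single read,
so its genomic arrangement is inferred from k-mer spacing within reads: the
monomer is tiled with non-overlapping 12-mers and, for every read containing
the anchor (the position-0 tiling 12-mer, up to one substitution), the
signed offsets and orientations of the other tiling 12-mers on that read
are accumulated.  In a head-to-tail tandem array the offsets concentrate on
a predictable set (intra-monomer offsets plus negative, junction-wrapped
ones) in a consistent orientation; inverted (head-to-head) arrangements
flip orientations, and dispersed single copies never show wrapped offsets.

Abundance uses non-overlapping 18-mers: after adjusting the observed k-mer
count for read coverage — a base sampled at depth c yields k-mer depth
c*(R-k+1)/R — the mean over tiling 18-mers estimates genomic copy number.
"Variable" copy numbers additionally count all single-substitution,
single-insertion and single-deletion neighbours of each tiling 18-mer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    deletion_neighbors,
    encode,
    encode_kmer,
    insertion_neighbors,
    kmer_codes_with_pos,
    revcomp,
    substitution_neighbors,
)
from .kmers import KmerTable

_CHUNK_READS = 4000


@dataclass
class SatelliteModel:
    """A satellite family: monomer plus the read-length context."""

    id: str
    monomer: str
    read_len: int = 100
    k_arrange: int = 12
    k_abund: int = 18

    def __post_init__(self) -> None:
        if not 100 <= len(self.monomer) <= 300:
            raise ValueError("monomer length must be in [100, 300]")

    @property
    def length(self) -> int:
        return len(self.monomer)

    def tiling(self, k: int | None = None) -> list[tuple[int, str]]:
        """Non-overlapping tiling k-mers from position 0: floor(L/k) of them."""
        k = k or self.k_arrange
        return [
            (p, self.monomer[p : p + k])
            for p in range(0, self.length - k + 1, k)
        ]


def expected_cooccurrence(read_len: int, k: int, offset: int) -> float:
    """Probability that a read containing a k-mer also fully contains a
    second k-mer starting ``offset`` bp away, under uniform read placement
    over a long array: (R-k-|d|+1)/(R-k+1), zero beyond |d| = R-k."""
    if k <= 0 or read_len <= k:
        raise ValueError("need read_len > k > 0")
    d = abs(offset)
    if d > read_len - k:
        return 0.0
    return (read_len - k - d + 1) / (read_len - k + 1)


def expected_offsets(model: SatelliteModel) -> list[int]:
    """Signed offsets at which tiling k-mers co-occur with the anchor on one
    read, assuming head-to-tail tandem arrays: each tiling position p maps to
    offsets p and p-L (modulo the monomer), kept when |d| <= R-k."""
    R, k, L = model.read_len, model.k_arrange, model.length
    out: set[int] = set()
    for p, _ in model.tiling():
        if p == 0:
            continue
        for d in (p, p - L):
            if 0 < abs(d) <= R - k:
                out.add(d)
    return sorted(out)


@dataclass
class CooccurrenceProfile:
    """Observed co-occurrence counts per (signed offset, orientation) in the
    anchor-forward frame, with the analytic expectation per expected offset."""

    anchor: str
    n_anchor_reads: int
    observed: Counter = field(default_factory=Counter)  # (offset, orient) -> n
    expected: dict[int, float] = field(default_factory=dict)
    classification: str = "not detected"

    def fraction_at_expected(self) -> float:
        total = sum(self.observed.values())
        if total == 0:
            return 0.0
        good = sum(
            n for (d, o), n in self.observed.items() if o == "+" and d in self.expected
        )
        return good / total


def _pattern_codes(kmer: str, max_mismatch: int) -> list[int]:
    pats = [kmer] + (substitution_neighbors(kmer) if max_mismatch >= 1 else [])
    return [encode_kmer(p) for p in pats]


def arrangement_profile(
    reads,
    model: SatelliteModel,
    max_mismatch: int = 1,
    tandem_threshold: float = 0.90,
    flip_threshold: float = 0.20,
    wrap_share: float = 0.5,
) -> CooccurrenceProfile:
    """Scan reads for the anchor 12-mer and score co-occurring tiling 12-mers.

    Classification: "head-to-tail tandem" when >= ``tandem_threshold`` of
    co-occurrences sit on the expected offsets in consistent orientation AND
    junction-wrapped (negative) offsets carry at least ``wrap_share`` of
    their analytically expected share; "head-to-head" when orientation flips
    exceed ``flip_threshold``; otherwise "dispersed".
    """
    k = model.k_arrange
    R = model.read_len
    tiling = model.tiling()
    # code -> (tile position, orientation relative to monomer forward strand)
    code_map: dict[int, tuple[int, str]] = {}
    for p, kmer in tiling:
        for c in _pattern_codes(kmer, max_mismatch):
            code_map.setdefault(c, (p, "+"))
        for c in _pattern_codes(revcomp(kmer), max_mismatch):
            code_map.setdefault(c, (p, "-"))
    anchor_fwd = {c for c, (p, o) in code_map.items() if p == 0 and o == "+"}
    anchor_rev = {c for c, (p, o) in code_map.items() if p == 0 and o == "-"}
    anchor_fwd_arr = np.fromiter(anchor_fwd, dtype=np.int64)
    anchor_rev_arr = np.fromiter(anchor_rev, dtype=np.int64)

    seqs = reads.seqs if hasattr(reads, "seqs") else [s for _, s in reads]
    profile = CooccurrenceProfile(anchor=model.monomer[:k], n_anchor_reads=0)
    for d in expected_offsets(model):
        profile.expected[d] = expected_cooccurrence(R, k, d)

    stride = R + 1
    interesting: list[tuple[str, bool]] = []  # (read, needs_revcomp)
    for start in range(0, len(seqs), _CHUNK_READS):
        chunk = seqs[start : start + _CHUNK_READS]
        concat = "N".join(chunk)
        codes, pos = kmer_codes_with_pos(encode(concat), k)
        if codes.size == 0:
            continue
        fwd_hit = np.isin(codes, anchor_fwd_arr)
        rev_hit = np.isin(codes, anchor_rev_arr)
        idx = np.unique(pos[fwd_hit | rev_hit] // stride)
        for i in idx:
            read = chunk[int(i)]
            # orient so that the anchor is on the forward strand of the read
            rcodes, rpos = kmer_codes_with_pos(encode(read), k)
            needs_rc = not np.isin(rcodes, anchor_fwd_arr).any()
            interesting.append((read, needs_rc))

    for read, needs_rc in interesting:
        working = revcomp(read) if needs_rc else read
        codes, pos = kmer_codes_with_pos(encode(working), k)
        hits = [
            (int(p), code_map[int(c)])
            for p, c in zip(pos, codes)
            if int(c) in code_map
        ]
        anchors = [p for p, (tile, o) in hits if tile == 0 and o == "+"]
        if not anchors:
            continue
        profile.n_anchor_reads += 1
        pa = anchors[0]
        for p, (tile, orient) in hits:
            if p == pa:
                continue
            profile.observed[(p - pa, orient)] += 1

    total = sum(profile.observed.values())
    if profile.n_anchor_reads == 0:
        profile.classification = "not detected"
        return profile
    if total == 0:
        profile.classification = "dispersed"
        return profile
    frac_expected = profile.fraction_at_expected()
    flipped = sum(n for (d, o), n in profile.observed.items() if o == "-") / total
    wrapped_obs = sum(
        n for (d, o), n in profile.observed.items() if o == "+" and d < 0 and d in profile.expected
    )
    exp_total = sum(profile.expected.values())
    exp_wrapped = sum(v for d, v in profile.expected.items() if d < 0)
    wrapped_frac = wrapped_obs / total
    exp_wrapped_share = exp_wrapped / exp_total if exp_total else 0.0
    if (
        frac_expected >= tandem_threshold
        and exp_wrapped_share > 0
        and wrapped_frac >= wrap_share * exp_wrapped_share
    ):
        profile.classification = "head-to-tail tandem"
    elif flipped >= flip_threshold:
        profile.classification = "head-to-head"
    else:
        profile.classification = "dispersed"
    return profile


@dataclass
class AbundanceEstimate:
    """Copy-number estimate for one satellite family."""

    canonical: float
    variable: float
    monomer_len: int

    @property
    def total_span_mbp(self) -> float:
        """Genomic span of the family: monomer length x variable copies."""
        return self.monomer_len * self.variable / 1e6


def satellite_span_mbp(monomer_len: int, variable_count: float) -> float:
    """Total genomic extent of a satellite family in Mbp."""
    return monomer_len * variable_count / 1e6


def _canonical_code(kmer: str) -> int:
    c = encode_kmer(kmer)
    rc = encode_kmer(revcomp(kmer))
    return min(c, rc)


def estimate_abundance(
    table: KmerTable,
    model: SatelliteModel,
    per_base_depth: float,
    read_len: int | None = None,
    table_del: KmerTable | None = None,
    table_ins: KmerTable | None = None,
) -> AbundanceEstimate:
    """Copy numbers from tiling 18-mer frequencies in a canonical-strand
    k-mer table.  ``table_del``/``table_ins`` (k-1 and k+1 tables from the
    same reads) enable counting single-indel variants as well."""
    if per_base_depth <= 0:
        raise ValueError("per-base depth must be positive")
    k = table.k
    R = read_len or model.read_len

    def kdepth(kk: int) -> float:
        return per_base_depth * (R - kk + 1) / R

    # neighbours that occur verbatim in the canonical tandem context would
    # re-count canonical copies; screen against the doubled monomer
    doubled = model.monomer + model.monomer
    doubled_rc = revcomp(doubled)

    def in_canonical(s: str) -> bool:
        return s in doubled or s in doubled_rc

    canon_ests, var_ests = [], []
    for p, kmer in model.tiling(k):
        exact = table.get_code(_canonical_code(kmer))
        canon = exact / kdepth(k)
        var = canon
        seen = {kmer}
        for nb in substitution_neighbors(kmer):
            if nb not in seen and not in_canonical(nb):
                seen.add(nb)
                var += table.get_code(_canonical_code(nb)) / kdepth(k)
        if table_del is not None:
            for nb in deletion_neighbors(kmer):
                if not in_canonical(nb):
                    var += table_del.get_code(_canonical_code(nb)) / kdepth(k - 1)
        if table_ins is not None:
            for nb in insertion_neighbors(kmer):
                if not in_canonical(nb):
                    var += table_ins.get_code(_canonical_code(nb)) / kdepth(k + 1)
        canon_ests.append(canon)
        var_ests.append(var)
    canonical = float(np.mean(canon_ests)) if canon_ests else 0.0
    variable = float(np.mean(var_ests)) if var_ests else 0.0
    return AbundanceEstimate(
        canonical=canonical, variable=max(variable, canonical), monomer_len=model.length
    )
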