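"""Lightweight seed-and-extend read mapper and the Alignment contract.

The mapper indexes exact seeds (default 19 bp) of the reference, collects
candidate diagonals from seed hits on either strand, scores each candidate
— an ungapped fast path for near-exact placements, otherwise an affine
gapped alignment (match +1, mismatch -1, gap open -3, gap extend -1 with
free reference overhangs) — and reports the best-scoring placement.
Mapping quality encodes uniqueness only: a unique best placement gets
q = 60, tied placements get q = 0 (the leftmost is reported).

Downstream stages depend only on the :class:`Alignment` contract, so an
external mapper's SAM output can be imported instead (see ``seqio``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, kmer_codes_with_pos, mismatch_count, revcomp

_SPACER = 200  # N run between concatenated scaffolds; longer than any read


def _aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -3.0
    a.extend_gap_score = -1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a.end_deletion_score = 0.0  # reference-window overhangs are free
    return a


@dataclass
class Alignment:
    """A gapped placement of a read on a reference scaffold.

    ``cigar`` uses ops M (aligned, match or mismatch), I (insertion to the
    reference), D (deletion from the reference) and S (soft-clipped read
    bases at either end); M+I+S consume exactly the read length.  ``seq`` is
    the full read oriented to the reference strand.  ``nm`` counts
    mismatches plus inserted plus deleted bases over the aligned part.
    """

    read_id: str
    ref_id: str
    ref_start: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    mapq: int
    nm: int
    seq: str
    score: float = 0.0

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def read_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def is_gapped(self) -> bool:
        return any(op in "ID" for op, _ in self.cigar)

    def is_clipped(self) -> bool:
        return any(op == "S" for op, _ in self.cigar)

    @property
    def aligned_seq(self) -> str:
        """Read bases inside the aligned (unclipped) part."""
        lead = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        tail = self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0
        return self.seq[lead : len(self.seq) - tail]


class ReferenceIndex:
    """Exact-seed index over one or more scaffolds."""

    def __init__(self, reference: dict[str, str] | str, seed_len: int = 19):
        if isinstance(reference, str):
            reference = {"ref": reference}
        self.seed_len = seed_len
        self.names = list(reference)
        self.offsets: dict[str, int] = {}
        parts = []
        off = 0
        for name in self.names:
            seq = reference[name].upper()
            self.offsets[name] = off
            parts.append(seq)
            off += len(seq)
            parts.append("N" * _SPACER)
            off += _SPACER
        self.concat = "".join(parts)
        self.codes = encode(self.concat)
        self.lengths = {n: len(reference[n]) for n in self.names}
        kc, pos = kmer_codes_with_pos(self.codes, seed_len)
        order = np.argsort(kc, kind="stable")
        self._sorted = kc[order]
        self._pos = pos[order].astype(np.int64)
        # scaffold lookup: sorted start offsets
        self._starts = np.array([self.offsets[n] for n in self.names], dtype=np.int64)

    def seed_hits(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted, code, side="left")
        hi = np.searchsorted(self._sorted, code, side="right")
        return self._pos[lo:hi]

    def locate(self, global_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._starts, global_pos, side="right")) - 1
        name = self.names[i]
        return name, global_pos - self.offsets[name]


_BATCH = 10000


def _rolling_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes over a (possibly N-containing) code array plus a
    validity mask; invalid (N-containing) windows hold garbage codes."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = codes.astype(np.int64)
    roll = np.zeros(n, dtype=np.int64)
    for j in range(k):
        roll = (roll << 2) | (vals[j : j + n] & 3)
    bad = (codes == 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return roll, valid


def _batch_seed_hits(batch, index: "ReferenceIndex", seed_len: int):
    """Vectorised seed lookup for a batch of reads.

    Returns, per read, a list of (strand, oriented_seq, [(offset, hits)]).
    """
    entries: list[tuple[int, str, str]] = []
    for i, (_rid, seq) in enumerate(batch):
        if len(seq) >= seed_len:
            entries.append((i, "+", seq))
            entries.append((i, "-", revcomp(seq)))
    results: list[list] = [[] for _ in batch]
    if not entries:
        return results
    concat = "N".join(e[2] for e in entries)
    roll, valid = _rolling_codes(encode(concat), seed_len)
    meta: list[tuple[int, int]] = []
    codes_list: list[int] = []
    base = 0
    for ei, (_i, _strand, seq) in enumerate(entries):
        rlen = len(seq)
        offs = list(range(0, rlen - seed_len + 1, seed_len))
        if offs and offs[-1] != rlen - seed_len:
            offs.append(rlen - seed_len)
        for o in offs:
            p = base + o
            if p < valid.size and valid[p]:
                meta.append((ei, o))
                codes_list.append(int(roll[p]))
        base += rlen + 1
    per_entry: list[list] = [[] for _ in entries]
    if codes_list:
        codes_arr = np.asarray(codes_list, dtype=np.int64)
        lo = np.searchsorted(index._sorted, codes_arr, side="left")
        hi = np.searchsorted(index._sorted, codes_arr, side="right")
        for j in np.flatnonzero(hi > lo):
            ei, o = meta[j]
            per_entry[ei].append((o, index._pos[lo[j] : hi[j]]))
    for ei, (i, strand, seq) in enumerate(entries):
        results[i].append((strand, seq, per_entry[ei]))
    return results


def _cigar_from_blocks(tblocks, qblocks, read_len: int) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    # leading unaligned query (should not occur with global query) -> I
    if qblocks[0][0] > 0:
        ops.append(("I", int(qblocks[0][0])))
    for i, (tb, qb) in enumerate(zip(tblocks, qblocks)):
        if i > 0:
            dt = int(tb[0] - tblocks[i - 1][1])
            dq = int(qb[0] - qblocks[i - 1][1])
            if dq > 0:
                ops.append(("I", dq))
            if dt > 0:
                ops.append(("D", dt))
        ops.append(("M", int(tb[1] - tb[0])))
    if qblocks[-1][1] < read_len:
        ops.append(("I", int(read_len - qblocks[-1][1])))
    # merge adjacent same ops
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def _solid_end_strip(state: list[int]) -> int | None:
    """Columns to strip from the front of ``state`` (1 match, 0 mismatch,
    -1 indel) so that it starts with an acceptable solid structure:
    either an exact-match run >= 6, or a terminal run >= 2 followed by one
    mismatch and a second run with combined length >= 12.  None when no
    acceptable start exists."""
    n = len(state)
    j = 0
    while j < n:
        if state[j] != 1:
            j += 1
            continue
        k = j
        while k < n and state[k] == 1:
            k += 1
        r1 = k - j
        if r1 >= 6:
            return j
        if r1 >= 2 and k < n and state[k] == 0:
            m = k + 1
            while m < n and state[m] == 1:
                m += 1
            if r1 + (m - k - 1) >= 12:
                return j
        j = k
    return None


def _trim_alignment(cigar, gpos, oriented, concat, min_anchor: int = 25):
    """Soft-clip poorly matching alignment ends (bwa-mem-like behaviour).

    Columns are scored match +1, mismatch -1, indel -(2+len); the maximal
    scoring contiguous stretch is kept, the ends become S ops.  Terminal
    aligned blocks shorter than ``min_anchor`` that hang beyond an indel are
    pruned as well — chance micro-alignments of a read tail inside a
    deleted region would otherwise fragment genuine zero-coverage runs.
    Returns (cigar, gpos, nm, kept score) or None when nothing remains.
    """
    cols: list[tuple[str, int, int, int]] = []  # op, read-consumed, ref-consumed, score
    rpos, qpos = gpos, 0
    for op, n in cigar:
        if op == "M":
            for j in range(n):
                match = concat[rpos + j] == oriented[qpos + j]
                cols.append(("M", 1, 1, 1 if match else -1))
            rpos += n
            qpos += n
        elif op == "I":
            cols.append(("I", n, 0, -(2 + n)))
            qpos += n
        elif op == "D":
            cols.append(("D", 0, n, -(2 + n)))
            rpos += n
    # maximal-scoring subarray; score ties extend the current stretch
    best_sum, best = 0, None
    run_sum, run_start = 0, 0
    for i, (_op, _rc, _fc, sc) in enumerate(cols):
        if run_sum < 0:
            run_sum, run_start = 0, i
        run_sum += sc
        if run_sum > best_sum or (
            best is not None
            and run_sum == best_sum
            and run_start == best[0]
            and i > best[1]
        ):
            best_sum, best = run_sum, (run_start, i)
    if best is None:
        return None
    i0, i1 = best

    # prune terminal aligned blocks < min_anchor hanging beyond an indel
    def block_spans(lo, hi):
        """(start, end, aligned length) of contiguous M runs in cols[lo..hi]."""
        spans = []
        j = lo
        while j <= hi:
            if cols[j][0] == "M":
                k = j
                while k + 1 <= hi and cols[k + 1][0] == "M":
                    k += 1
                spans.append((j, k, k - j + 1))
                j = k + 1
            else:
                j += 1
        return spans

    changed = True
    while changed and i0 <= i1:
        changed = False
        spans = block_spans(i0, i1)
        if len(spans) >= 2:
            if spans[0][2] < min_anchor:
                i0 = spans[1][0]
                changed = True
            elif spans[-1][2] < min_anchor:
                i1 = spans[-2][1]
                changed = True
    # solid-end rule: each end must close with >= 6 exact matches, or a
    # short (>= 2) terminal run separated by one mismatch from a long run
    # (combined >= 12) — allows a real substitution right next to a
    # breakpoint without letting chance tail matches through
    state = [
        (1 if c[3] > 0 else 0) if c[0] == "M" else -1 for c in cols[i0 : i1 + 1]
    ]
    tail = _solid_end_strip(state[::-1])
    head = _solid_end_strip(state)
    if tail is None or head is None:
        return None
    i0n, i1n = i0 + head, i1 - tail
    if i1n < i0n:
        return None
    i0, i1 = i0n, i1n
    if not any(c[0] == "M" for c in cols[i0 : i1 + 1]):
        return None
    kept_score = float(sum(c[3] for c in cols[i0 : i1 + 1]))
    lead_clip = sum(c[1] for c in cols[:i0])
    tail_clip = sum(c[1] for c in cols[i1 + 1 :])
    new_gpos = gpos + sum(c[2] for c in cols[:i0])
    ops: list[tuple[str, int]] = []
    if lead_clip:
        ops.append(("S", lead_clip))
    nm = 0
    for op, rc, fc, sc in cols[i0 : i1 + 1]:
        if op == "M":
            nm += sc < 0
            n = 1
        else:
            nm += max(rc, fc)
            n = max(rc, fc)
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))
    if tail_clip:
        ops.append(("S", tail_clip))
    return ops, new_gpos, nm, kept_score


def _trim_ungapped(ref_codes: np.ndarray, diag: int, rcodes: np.ndarray):
    """Vectorised equivalent of :func:`_trim_alignment` for an ungapped
    placement: maximal +-1-scoring stretch with solid ends.
    Returns (cigar, gpos, nm, score) or None."""
    n = rcodes.size
    match = ref_codes[diag : diag + n] == rcodes
    if match.size != n:
        return None
    s = np.where(match, 1, -1).astype(np.int64)
    P = np.concatenate(([0], np.cumsum(s)))
    minpre = np.minimum.accumulate(P[:-1])
    val = P[1:] - minpre
    e = n - 1 - int(np.argmax(val[::-1]))  # ties -> longest stretch
    if val[e] <= 0:
        return None
    target = minpre[e]
    start = int(np.argmax(P[: e + 1] == target))
    i0, i1 = start, e  # columns [i0, i1] inclusive
    state = match[i0 : i1 + 1].astype(np.int8).tolist()
    head = _solid_end_strip(state)
    tail = _solid_end_strip(state[::-1])
    if head is None or tail is None:
        return None
    i0, i1 = i0 + head, i1 - tail
    if i1 < i0:
        return None
    nm = int(np.count_nonzero(~match[i0 : i1 + 1]))
    score = float((i1 - i0 + 1) - 2 * nm)
    ops: list[tuple[str, int]] = []
    if i0:
        ops.append(("S", i0))
    ops.append(("M", i1 - i0 + 1))
    if i1 < n - 1:
        ops.append(("S", n - 1 - i1))
    return ops, diag + i0, nm, score


def map_reads(
    reads,
    reference: dict[str, str] | str | ReferenceIndex,
    seed_len: int = 19,
    max_mismatches: int | None = None,
    max_candidates: int = 64,
    pad: int = 120,
    tie_period: dict[str, int] | None = None,
) -> list[Alignment]:
    """Map every read; reads shorter than the seed are left unmapped.

    ``reads`` is a ``ReadSet`` or an iterable of ``(id, sequence)`` pairs.
    When ``max_mismatches`` is given, alignments with NM above it are
    dropped.  Reads whose seeds hit more than ``max_candidates`` distinct
    diagonals are reported at the first evaluated placements with q = 0.
    ``tie_period`` maps scaffold name to a tandem period: tied placements on
    that scaffold congruent modulo the period are one placement (used when
    mapping against tandem-tiled repeat units).
    """
    index = (
        reference
        if isinstance(reference, ReferenceIndex)
        else ReferenceIndex(reference, seed_len)
    )
    seed_len = index.seed_len
    aligner = _aligner()
    out: list[Alignment] = []
    ref_codes = index.codes
    concat = index.concat
    n_concat = len(concat)

    pairs = list(reads) if not isinstance(reads, list) else reads
    for batch_start in range(0, len(pairs), _BATCH):
        batch = pairs[batch_start : batch_start + _BATCH]
        seed_table = _batch_seed_hits(batch, index, seed_len)
        for bi, (read_id, seq) in enumerate(batch):
            rlen = len(seq)
            if rlen < seed_len:
                continue
            capped = False
            # pass 1: fast/ungapped evaluation of every candidate diagonal
            cands: list[tuple] = []  # (score, gpos, strand, cigar, nm, oriented)
            pending: list[tuple] = []  # (diag, strand, oriented, ungapped|None)
            for strand, oriented, hit_lists in seed_table[bi]:
                diags: set[int] = set()
                for o, hits in hit_lists:
                    for hit in hits:
                        diags.add(int(hit) - o)
                    if len(diags) > max_candidates:
                        capped = True
                        break
                if not diags:
                    continue
                rcodes = encode(oriented)
                for diag in sorted(diags)[: (16 if capped else max_candidates)]:
                    if diag < 0 or diag + rlen > n_concat:
                        continue
                    mm = mismatch_count(ref_codes, diag, rcodes)
                    if mm <= max(2, rlen // 25):
                        diffs = np.flatnonzero(ref_codes[diag : diag + rlen] != rcodes)
                        if mm > 0 and (
                            diffs[0] <= 2 or diffs[-1] >= rlen - 3 or mm > 4
                        ):
                            t = _trim_ungapped(ref_codes, diag, rcodes)
                            if t is None:
                                continue
                            cigar_t, gpos_t, nm_t, score_t = t
                            cands.append((score_t, gpos_t, strand, cigar_t, nm_t, oriented))
                        else:
                            cands.append(
                                (float(rlen - 2 * mm), diag, strand, [("M", rlen)], mm, oriented)
                            )
                        continue
                    ungapped = _trim_ungapped(ref_codes, diag, rcodes)
                    if ungapped is not None:
                        cigar_t, gpos_t, nm_t, score_t = ungapped
                        cands.append((score_t, gpos_t, strand, cigar_t, nm_t, oriented))
                    if not capped and not (
                        ungapped is not None and ungapped[3] >= rlen - 3
                    ):
                        pending.append((diag, strand, oriented, ungapped))
            # pass 2: gapped alignment only where it could beat the best so
            # far — rejoining a clipped tail can add at most (clip - 3)
            best_so_far = max((c[0] for c in cands), default=float("-inf"))
            for diag, strand, oriented, ungapped in pending:
                clip = rlen if ungapped is None else rlen - sum(
                    n for op, n in ungapped[0] if op in "MI"
                )
                bound = (0.0 if ungapped is None else ungapped[3]) + clip - 3
                if bound <= best_so_far:
                    continue
                w0 = max(0, diag - pad)
                w1 = min(n_concat, diag + rlen + pad)
                window = concat[w0:w1]
                aln = aligner.align(window, oriented)[0]
                tb, qb = aln.aligned
                if len(tb) == 0:
                    continue
                cigar_g = _cigar_from_blocks(tb, qb, rlen)
                gapped = _trim_alignment(cigar_g, w0 + int(tb[0][0]), oriented, concat)
                if gapped is None:
                    continue
                cigar_t, gpos_t, nm_t, score_t = gapped
                cands.append((score_t, gpos_t, strand, cigar_t, nm_t, oriented))
                best_so_far = max(best_so_far, score_t)
            if not cands:
                continue
            best_score = max(c[0] for c in cands)
            best_list = sorted(
                (c[1:] for c in cands if c[0] == best_score), key=lambda c: c[0]
            )
            gpos, strand, cigar, nm, oriented = best_list[0]
            if max_mismatches is not None and nm > max_mismatches:
                continue
            ref_id, start = index.locate(gpos)
            if start + sum(n for op, n in cigar if op in "MD") > index.lengths[ref_id]:
                continue  # would cross a scaffold spacer
            seen = {gpos}
            n_distinct = 1
            for other in best_list[1:]:
                if other[0] in seen:
                    continue
                seen.add(other[0])
                oref, opos = index.locate(other[0])
                period = (tie_period or {}).get(oref, 0)
                if oref == ref_id and period and (opos - start) % period == 0:
                    continue
                n_distinct += 1
            mapq = 0 if (capped or n_distinct > 1) else 60
            out.append(
                Alignment(read_id, ref_id, start, strand, cigar, mapq, nm, oriented, float(best_score))
            )
    return out
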