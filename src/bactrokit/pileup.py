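"""Per-base pileups and depth tracks built from Alignment lists.

Only alignments passing the mapping-quality filter contribute; a read's
deletion operation contributes no base (and no depth) at the deleted
reference positions, mirroring how per-base coverage utilities treat
spliced/deleted segments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode
from .mapping import Alignment

_CHUNK = 20000


class Pileup:
    """Base counts by allele per reference position, plus indel evidence.

    ``counts[ref_id]`` has shape (4, L) in A,C,G,T order; ``depth`` at a
    site is the column sum.  ``insertions[(ref_id, pos)]`` counts inserted
    sequences anchored *before* ``pos``; ``deletions[(ref_id, pos, length)]``
    counts reads whose deletion op starts at ``pos``.  ``del_span[ref_id]``
    counts reads spanning each position with a deletion op (used as the
    denominator complement for indel frequencies).
    """

    def __init__(self, ref_lengths: dict[str, int]):
        self.ref_lengths = dict(ref_lengths)
        self.counts = {n: np.zeros((4, L), dtype=np.int32) for n, L in ref_lengths.items()}
        self.del_span = {n: np.zeros(L, dtype=np.int32) for n, L in ref_lengths.items()}
        self.insertions: Counter = Counter()
        self.deletions: Counter = Counter()

    def depth(self, ref_id: str) -> np.ndarray:
        return self.counts[ref_id].sum(axis=0)

    def base_counts(self, ref_id: str, pos: int) -> dict[str, int]:
        col = self.counts[ref_id][:, pos]
        return {b: int(c) for b, c in zip("ACGT", col)}


def pileup_from_alignments(
    alignments: list[Alignment],
    ref_lengths: dict[str, int],
    min_q: int = 20,
) -> Pileup:
    """Accumulate a pileup from alignments with mapq strictly above ``min_q``.

    Ungapped (pure-M) alignments are accumulated in vectorised batches;
    gapped ones are walked op by op.
    """
    pile = Pileup(ref_lengths)
    batches: dict[str, tuple[list, list]] = {n: ([], []) for n in ref_lengths}

    def flush(ref_id: str) -> None:
        pos_list, code_list = batches[ref_id]
        if not pos_list:
            return
        L = pile.ref_lengths[ref_id]
        pos = np.concatenate(pos_list)
        codes = np.concatenate(code_list)
        ok = codes < 4
        flat = codes[ok].astype(np.int64) * L + pos[ok]
        bc = np.bincount(flat, minlength=4 * L)
        pile.counts[ref_id] += bc.reshape(4, L).astype(np.int32)
        batches[ref_id] = ([], [])

    for aln in alignments:
        if aln.mapq <= min_q:
            continue
        codes = encode(aln.seq)
        if not aln.is_gapped() and not aln.is_clipped():
            n = len(aln.seq)
            pos_list, code_list = batches[aln.ref_id]
            pos_list.append(np.arange(aln.ref_start, aln.ref_start + n, dtype=np.int64))
            code_list.append(codes)
            if len(pos_list) >= _CHUNK:
                flush(aln.ref_id)
            continue
        rpos, qpos = aln.ref_start, 0
        counts = pile.counts[aln.ref_id]
        for op, n in aln.cigar:
            if op == "M":
                for j in range(n):
                    c = codes[qpos + j]
                    if c < 4:
                        counts[c, rpos + j] += 1
                rpos += n
                qpos += n
            elif op == "S":
                qpos += n
            elif op == "I":
                pile.insertions[(aln.ref_id, rpos, aln.seq[qpos : qpos + n])] += 1
                qpos += n
            elif op == "D":
                pile.deletions[(aln.ref_id, rpos, n)] += 1
                pile.del_span[aln.ref_id][rpos : rpos + n] += 1
                rpos += n
    for name in ref_lengths:
        flush(name)
    return pile


@dataclass
class CoverageTrack:
    """Per-base depth over reference scaffolds (deleted segments uncovered)."""

    depth: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_alignments(
        cls,
        alignments: list[Alignment],
        ref_lengths: dict[str, int],
        min_q: int = 20,
        paired_only: bool = False,
    ) -> "CoverageTrack":
        """Depth via interval stabbing (difference arrays); a deletion op
        leaves its span uncovered.  With ``paired_only``, only reads whose
        mate also mapped (ids ``x/1`` and ``x/2``) contribute."""
        keep = alignments
        if paired_only:
            mapped = {a.read_id for a in alignments}

            def mate(rid: str) -> str:
                if rid.endswith("/1"):
                    return rid[:-2] + "/2"
                if rid.endswith("/2"):
                    return rid[:-2] + "/1"
                return rid

            keep = [a for a in alignments if mate(a.read_id) in mapped]
        diffs = {n: np.zeros(L + 1, dtype=np.int32) for n, L in ref_lengths.items()}
        for aln in keep:
            if aln.mapq <= min_q:
                continue
            d = diffs[aln.ref_id]
            rpos = aln.ref_start
            for op, n in aln.cigar:
                if op == "M":
                    d[rpos] += 1
                    d[rpos + n] -= 1
                    rpos += n
                elif op == "D":
                    rpos += n
        return cls({n: np.cumsum(d[:-1]).astype(np.int32) for n, d in diffs.items()})
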