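"""Structural divergence between sibling species: zero-coverage deletion
calling with flank filters, the repeat-association permutation test, and
the transposon insert-span comparison against matched random controls.

Deletions are detected as maximal runs of exactly zero coverage longer than
10 bp in the mapping of sibling reads onto the reference, retained only
when every one of the 10 bases immediately bordering the run on both sides
exceeds the flank depth floor — the strictest reading of "high, precisely
aligned coverage on both sides".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import kmer_codes, encode, revcomp
from .mapping import ReferenceIndex, map_reads
from .pileup import CoverageTrack


@dataclass
class DeletionCall:
    """A zero-coverage interval (0-based half-open) passing both flank
    filters; flank minima are over the 10 bases bordering each side."""

    scaffold: str
    start: int
    end: int
    left_min_cov: int
    right_min_cov: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _zero_runs(depth: np.ndarray) -> list[tuple[int, int]]:
    iszero = np.concatenate(([0], (depth == 0).astype(np.int8), [0]))
    d = np.diff(iszero)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _denoise(
    depth: np.ndarray,
    noise_cov: int,
    noise_len: int,
    shoulder_frac: float = 0.35,
) -> np.ndarray:
    """Suppress breakpoint artefacts that erode genuine zero-coverage runs.

    Two patterns are zeroed next to (or between) zero stretches: short
    islands at absolute depth <= ``noise_cov`` (a sequencing error at a
    breakpoint-adjacent base recreates the reference allele in single
    reads), and "shoulders" whose depth is <= ``shoulder_frac`` of the
    local flank depth (the minority of junction reads that soft-clip
    rather than carry a deletion op extends a few micro-homology bases
    past the breakpoint).  Both are limited to ``noise_len`` bases per
    side and never touch well-supported coverage.
    """
    out = depth.copy()
    low = (depth > 0) & (depth <= noise_cov)
    i = 0
    n = depth.size
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            left_zero = i == 0 or depth[i - 1] == 0
            right_zero = j == n or depth[j] == 0
            if j - i <= noise_len and (left_zero or right_zero):
                out[i:j] = 0
            i = j
        else:
            i += 1
    # shoulder pass: walk outward from every zero run, zeroing bases whose
    # depth is far below the local flank level
    iszero = np.concatenate(([0], (out == 0).astype(np.int8), [0]))
    d = np.diff(iszero)
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        # leftward
        k = int(s) - 1
        ref_lo = max(0, k - noise_len - 20)
        local = np.median(out[ref_lo : max(ref_lo + 1, k - noise_len + 1)])
        limit = max(noise_cov, shoulder_frac * local)
        steps = 0
        while k >= 0 and steps < noise_len and 0 < out[k] <= limit:
            out[k] = 0
            k -= 1
            steps += 1
        # rightward
        k = int(e)
        ref_hi = min(out.size, k + noise_len + 21)
        local = np.median(out[min(out.size - 1, k + noise_len) : ref_hi])
        limit = max(noise_cov, shoulder_frac * local)
        steps = 0
        while k < out.size and steps < noise_len and 0 < out[k] <= limit:
            out[k] = 0
            k += 1
            steps += 1
    return out


def find_deletions(
    coverage: CoverageTrack,
    min_len: int = 10,
    flank_len: int = 10,
    flank_min_cov: int = 20,
    noise_cov: int = 2,
    noise_len: int = 8,
) -> tuple[list[DeletionCall], dict]:
    """Maximal zero-coverage runs strictly longer than ``min_len`` whose
    two ``flank_len``-base borders are each entirely above ``flank_min_cov``.

    The track is first denoised: islands of <= ``noise_len`` bases at depth
    <= ``noise_cov`` bounded by zero coverage are treated as unsupported
    (set ``noise_cov=0`` to disable).  Returns the calls (sorted by
    scaffold, start) and filter statistics: candidate runs, flank-filter
    rejections and scaffold-edge rejections.
    """
    calls: list[DeletionCall] = []
    n_candidates = n_edge = n_flank = 0
    for scaffold in sorted(coverage.depth):
        depth = coverage.depth[scaffold]
        if noise_cov > 0:
            depth = _denoise(depth, noise_cov, noise_len)
        for s, e in _zero_runs(depth):
            if e - s <= min_len:
                continue
            n_candidates += 1
            if s < flank_len or e + flank_len > depth.size:
                n_edge += 1
                continue
            left = int(depth[s - flank_len : s].min())
            right = int(depth[e : e + flank_len].min())
            if left > flank_min_cov and right > flank_min_cov:
                calls.append(DeletionCall(scaffold, int(s), int(e), left, right))
            else:
                n_flank += 1
    stats_d = {
        "candidates_over_min_len": n_candidates,
        "rejected_flank_filter": n_flank,
        "rejected_scaffold_edge": n_edge,
        "retained": len(calls),
    }
    return calls, stats_d


def deletions_to_bed(calls: list[DeletionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": c.scaffold, "start": c.start, "end": c.end,
             "name": f"del_{i}", "score": c.length,
             "strand": "+", "left_min_cov": c.left_min_cov,
             "right_min_cov": c.right_min_cov}
            for i, c in enumerate(calls)
        ]
    )


# ---------------------------------------------------------------------------
# repeat-association permutation test


def repeat_hit_mask(
    assembly: str,
    repeat_lib: list[str],
    k: int = 12,
    window: int = 80,
    min_shared: int = 5,
) -> np.ndarray:
    """Boolean per-base mask of assembly positions inside a repeat match.

    A blast-like surrogate: positions where >= ``min_shared`` library
    12-mers (either strand) land within an ``window``-bp span are marked —
    tuned so an 80% identity, 80 bp alignment is detected.
    """
    lib_codes = set()
    for seq in repeat_lib:
        for s in (seq, revcomp(seq)):
            lib_codes.update(kmer_codes(encode(s), k).tolist())
    codes = kmer_codes(encode(assembly), k)
    lib_arr = np.fromiter(lib_codes, dtype=np.int64)
    hit = np.isin(codes, lib_arr).astype(np.int32)
    # pad back to genome length (kmer positions = starts)
    full = np.zeros(len(assembly), dtype=np.int32)
    full[: hit.size] = hit
    cs = np.concatenate(([0], np.cumsum(full)))
    w = min(window, len(assembly))
    shared = cs[w:] - cs[:-w]
    mask = np.zeros(len(assembly), dtype=bool)
    starts = np.flatnonzero(shared >= min_shared)
    for s in starts:
        mask[s : s + w] = True
    return mask


@dataclass
class AssociationResult:
    observed_fraction: float
    null_mean: float
    null_sd: float
    p_value: float
    n_flanks: int
    n_permutations: int


def repeat_association_test(
    calls: list[DeletionCall],
    assembly: str,
    repeat_lib: list[str],
    n_perm: int = 1000,
    identity: float = 0.80,
    min_hit: int = 80,
    flank: int = 1000,
    seed: int = 0,
) -> AssociationResult:
    """Are deletions preferentially flanked by repetitive sequence?

    The observed statistic is the fraction of the deletions' ``flank``-bp
    adjacent segments containing a repeat hit.  The null is built from
    ``n_perm`` sets of the same number of random genomic positions, each
    pseudo-deletion's two flanks separated by the matching real deletion's
    length (positions drawn independently, with replacement); p is the
    one-sided fraction of null statistics >= observed, with add-one
    correction.
    """
    if not calls:
        raise ValueError("nothing to test: no deletion calls")
    rng = np.random.default_rng(seed)
    mask = repeat_hit_mask(assembly, repeat_lib, min_shared=max(2, int(min_hit * identity) // 14))
    cs = np.concatenate(([0], np.cumsum(mask)))
    L = mask.size

    def frac_hit(starts: np.ndarray, ends: np.ndarray) -> float:
        hits = 0
        n = 0
        for s, e in zip(starts, ends):
            for fs, fe in ((max(0, s - flank), s), (e, min(L, e + flank))):
                if fe <= fs:
                    continue
                n += 1
                if cs[fe] - cs[fs] > 0:
                    hits += 1
        return hits / max(n, 1)

    starts = np.array([c.start for c in calls])
    ends = np.array([c.end for c in calls])
    lengths = ends - starts
    observed = frac_hit(starts, ends)
    null = np.empty(n_perm)
    for i in range(n_perm):
        s2 = rng.integers(0, L - lengths.max(), size=lengths.size)
        null[i] = frac_hit(s2, s2 + lengths)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return AssociationResult(
        observed_fraction=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_value=p,
        n_flanks=2 * len(calls),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# element merging and span comparison


@dataclass
class ElementSpan:
    """A merged (possibly fragmented) transposon element with its flanks."""

    id: str
    scaffold: str
    fragments: list[tuple[int, int]]
    start: int
    end: int
    span_sibling: int | None = None
    is_control: bool = False

    @property
    def span_ref(self) -> int:
        return self.end - self.start


def merge_elements(
    fragments: list[tuple[str, int, int]],
    merge_dist: int = 1500,
    canonical_len: int = 1500,
    flank: int = 1000,
    scaffold_lengths: dict[str, int] | None = None,
) -> tuple[list[ElementSpan], int]:
    """Transitively merge fragment hits within ``merge_dist``; merged extents
    reaching twice ``canonical_len`` are split at their largest internal gap.
    Elements whose ``flank`` would run past a scaffold edge are dropped and
    counted.  Returns (elements, n_dropped_at_edges)."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for sc, s, e in sorted(fragments):
        by_scaffold.setdefault(sc, []).append((s, e))
    elements: list[ElementSpan] = []
    dropped = 0
    eid = 0
    for sc, frags in by_scaffold.items():
        frags.sort()
        groups: list[list[tuple[int, int]]] = []
        for f in frags:
            if groups and f[0] - groups[-1][-1][1] <= merge_dist:
                groups[-1].append(f)
            else:
                groups.append([f])

        def emit(group: list[tuple[int, int]]) -> None:
            nonlocal eid, dropped
            start, end = group[0][0], group[-1][1]
            if end - start >= 2 * canonical_len and len(group) > 1:
                gaps = [group[i + 1][0] - group[i][1] for i in range(len(group) - 1)]
                gi = int(np.argmax(gaps))
                emit(group[: gi + 1])
                emit(group[gi + 1 :])
                return
            L = (scaffold_lengths or {}).get(sc)
            if start - flank < 0 or (L is not None and end + flank > L):
                dropped += 1
                return
            elements.append(ElementSpan(f"el{eid:04d}", sc, list(group), start, end))
            eid += 1

        for g in groups:
            emit(g)
    return elements, dropped


@dataclass
class SpanComparison:
    table: pd.DataFrame
    element_mean_abs_change: float
    control_mean_abs_change: float
    t_statistic: float
    p_value: float
    n_elements_measured: int
    n_elements_excluded: int


def _locate_pair(
    flank_a: str, flank_b: str, index: ReferenceIndex
) -> int | None:
    """Sibling distance between the inner edges of two flank sequences, or
    None when they do not land uniquely, consistently, on one contig."""
    hits = map_reads([("a", flank_a), ("b", flank_b)], index)
    by_id = {a.read_id: a for a in hits if a.mapq > 0}
    if "a" not in by_id or "b" not in by_id:
        return None
    a, b = by_id["a"], by_id["b"]
    if a.ref_id != b.ref_id or a.strand != b.strand:
        return None
    # demand confident homology: a repeat-dominated flank can land on the
    # wrong copy with a respectable score, so near-full-length, low-divergence
    # placements are required before a distance is trusted
    for aln, flank in ((a, flank_a), (b, flank_b)):
        clip = sum(n for op, n in aln.cigar if op == "S")
        if clip > 0.1 * len(flank) or aln.nm > 0.02 * len(flank):
            return None

    def clips(aln):
        lead = aln.cigar[0][1] if aln.cigar[0][0] == "S" else 0
        tail = aln.cigar[-1][1] if aln.cigar[-1][0] == "S" else 0
        return lead, tail

    la, ta = clips(a)
    lb, tb = clips(b)
    if a.strand == "+":
        # inner edges: end of flank A (plus its clipped tail), start of B
        span = (b.ref_start - lb) - (a.ref_end + ta)
    else:
        span = (a.ref_start - la) - (b.ref_end + tb)
    return span if span >= 0 else None


def compare_spans(
    elements: list[ElementSpan],
    reference: str,
    sibling: dict[str, str] | str,
    flank: int = 1000,
    n_controls: int | None = None,
    seed: int = 0,
) -> SpanComparison:
    """Measure each element's flank-to-flank distance in the sibling and
    compare the absolute span changes against matched random controls.

    Controls are random reference positions whose paired flanks are
    separated by the same insert sizes as the elements; significance is a
    two-tailed Welch t-test on |span_sibling - span_reference|.
    """
    if isinstance(sibling, str):
        sibling = {"contig0": sibling}
    rng = np.random.default_rng(seed)
    index = ReferenceIndex(sibling, seed_len=19)
    rows = []
    excluded = 0
    for el in elements:
        fa = reference[el.start - flank : el.start]
        fb = reference[el.end : el.end + flank]
        span_sib = _locate_pair(fa, fb, index)
        if span_sib is None:
            excluded += 1
            continue
        el.span_sibling = span_sib
        rows.append(
            {"id": el.id, "group": "element", "span_ref": el.span_ref,
             "span_sibling": span_sib, "abs_change": abs(span_sib - el.span_ref)}
        )
    measured = [r for r in rows]
    n_controls = n_controls or len(measured)
    gaps = [r["span_ref"] for r in measured] or [0]
    L = len(reference)
    made = 0
    attempts = 0
    while made < n_controls and attempts < 50 * max(n_controls, 1):
        attempts += 1
        gap = int(gaps[made % len(gaps)])
        pos = int(rng.integers(flank, max(flank + 1, L - flank - gap)))
        fa = reference[pos - flank : pos]
        fb = reference[pos + gap : pos + gap + flank]
        if len(fa) < flank or len(fb) < flank:
            continue
        span_sib = _locate_pair(fa, fb, index)
        if span_sib is None:
            continue
        rows.append(
            {"id": f"ctrl{made:04d}", "group": "control", "span_ref": gap,
             "span_sibling": span_sib, "abs_change": abs(span_sib - gap)}
        )
        made += 1
    df = pd.DataFrame(
        rows, columns=["id", "group", "span_ref", "span_sibling", "abs_change"]
    )
    el_changes = df.loc[df.group == "element", "abs_change"].to_numpy(float)
    ct_changes = df.loc[df.group == "control", "abs_change"].to_numpy(float)
    if el_changes.size >= 2 and ct_changes.size >= 2:
        t, p = stats.ttest_ind(el_changes, ct_changes, equal_var=False)
    else:
        t, p = float("nan"), float("nan")
    return SpanComparison(
        table=df,
        element_mean_abs_change=float(el_changes.mean()) if el_changes.size else float("nan"),
        control_mean_abs_change=float(ct_changes.mean()) if ct_changes.size else float("nan"),
        t_statistic=float(t),
        p_value=float(p),
        n_elements_measured=int(el_changes.size),
        n_elements_excluded=excluded,
    )
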