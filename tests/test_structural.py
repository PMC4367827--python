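"""Deletion calling (with brute-force zero-run oracle), the association
permutation test, element merging and span comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bactrokit.mapping import map_reads
from bactrokit.pileup import CoverageTrack
from bactrokit.simulate import (
    SiblingSpec,
    derive_sibling,
    random_sequence,
    simulate_reads,
)
from bactrokit.structural import (
    DeletionCall,
    compare_spans,
    find_deletions,
    merge_elements,
    repeat_association_test,
)


def brute_zero_runs(depth, min_len, flank_len, flank_min):
    """Per-base scan oracle for find_deletions on one track."""
    out = []
    i = 0
    n = len(depth)
    while i < n:
        if depth[i] == 0:
            j = i
            while j < n and depth[j] == 0:
                j += 1
            if j - i > min_len and i >= flank_len and j + flank_len <= n:
                left = min(depth[i - flank_len : i])
                right = min(depth[j : j + flank_len])
                if left > flank_min and right > flank_min:
                    out.append((i, j))
            i = j
        else:
            i += 1
    return out


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 40), min_size=1, max_size=300))
def test_find_deletions_matches_bruteforce(depths):
    depth = np.array(depths, dtype=np.int32)
    track = CoverageTrack({"s": depth})
    calls, _stats = find_deletions(track, min_len=3, flank_len=4, flank_min_cov=10,
                                   noise_cov=0)
    assert [(c.start, c.end) for c in calls] == brute_zero_runs(depth, 3, 4, 10)


def test_single_read_island_denoised():
    """A 1-2 bp depth-1 island between zero runs does not split a deletion."""
    depth = np.full(300, 40, dtype=np.int32)
    depth[100:160] = 0
    depth[130] = 1
    calls, _stats = find_deletions(CoverageTrack({"s": depth}))
    assert [(c.start, c.end) for c in calls] == [(100, 160)]
    # but a well-supported island does split the run
    depth[130] = 5
    calls, _stats = find_deletions(CoverageTrack({"s": depth}))
    assert all(c.start != 100 or c.end != 160 for c in calls)


def test_flank_filter_rejects_low_coverage():
    depth = np.full(200, 15, dtype=np.int32)  # below the 20x flank floor
    depth[100:120] = 0
    calls, stats = find_deletions(CoverageTrack({"s": depth}))
    assert calls == []
    assert stats["rejected_flank_filter"] == 1


def test_edge_interval_rejected_and_counted():
    depth = np.full(100, 30, dtype=np.int32)
    depth[:20] = 0
    calls, stats = find_deletions(CoverageTrack({"s": depth}))
    assert calls == []
    assert stats["rejected_scaffold_edge"] == 1


def test_planted_deletion_recovered_end_to_end(small_genome):
    genome, truth = small_genome["genome"], small_genome["truth"]
    spec = SiblingSpec(n_random_deletions=5, deletion_length_range=(20, 60), seed=51)
    sib, st_truth = derive_sibling(genome, truth, spec)
    reads = simulate_reads(sib, 70, 100, error_rate=0.0, paired=True, seed=52)
    alns = map_reads(reads, genome)
    track = CoverageTrack.from_alignments(alns, {"ref": len(genome)},
                                          min_q=20, paired_only=True)
    calls, _stats = find_deletions(track)
    planted = st_truth.deletions
    hits = 0
    # breakpoint micro-homology legitimately shifts call boundaries by a
    # few bases, so coordinates are scored with a small slack
    for s, ln in planted:
        if any(abs(c.start - s) <= 6 and abs(c.length - ln) <= 8 for c in calls):
            hits += 1
    assert hits == len(planted)
    assert len(calls) <= len(planted) + 1


def test_identical_sibling_no_calls(small_genome):
    genome = small_genome["genome"]
    reads = simulate_reads(genome, 40, 100, error_rate=0.0, paired=True, seed=53)
    alns = map_reads(reads, genome)
    track = CoverageTrack.from_alignments(alns, {"ref": len(genome)},
                                          min_q=20, paired_only=True)
    calls, _stats = find_deletions(track)
    assert calls == []


# ---------------------------------------------------------------------------
# association test


@pytest.fixture(scope="module")
def repeat_genome():
    """~30% repeat content arranged in islands (tandem blocks of a 600 bp
    repeat separated by long unique stretches), so that containing a repeat
    is informative for a 1 kb flank rather than near-certain."""
    rng = np.random.default_rng(60)
    rep = random_sequence(600, rng)
    parts = []
    for _ in range(8):
        parts.append(random_sequence(17_000, rng))
        parts.append(rep * 12)  # 7.2 kb island
    parts.append(random_sequence(10_000, rng))
    return "".join(parts), rep


def test_association_null_on_random_placement(repeat_genome):
    genome, rep = repeat_genome
    rng = np.random.default_rng(61)
    starts = np.sort(rng.choice(len(genome) - 3000, size=40, replace=False) + 1500)
    calls = [DeletionCall("s", int(s), int(s) + 30, 30, 30) for s in starts]
    res = repeat_association_test(calls, genome, [rep], n_perm=300, seed=62)
    assert res.p_value > 0.05
    assert abs(res.observed_fraction - res.null_mean) < 3 * max(res.null_sd, 0.02)


def test_association_significant_next_to_repeats():
    """Positive control: sparse repeats (few % of the genome), every deletion
    placed immediately downstream of a copy."""
    rng = np.random.default_rng(63)
    rep = random_sequence(600, rng)
    parts, starts = [], []
    pos = 0
    for _ in range(20):
        # irregular spacing so no single circular shift re-aligns the whole
        # permuted set with the repeat lattice
        filler = random_sequence(int(rng.integers(6_000, 18_000)), rng)
        parts.append(filler)
        pos += len(filler)
        starts.append(pos)
        parts.append(rep)
        pos += len(rep)
    genome = "".join(parts) + random_sequence(3000, rng)
    calls = [DeletionCall("s", s + 620, s + 660, 30, 30) for s in starts]
    res = repeat_association_test(calls, genome, [rep], n_perm=1000, seed=64)
    assert res.observed_fraction == 1.0
    assert res.null_mean < 0.3
    assert res.p_value <= 0.001 + 1e-9


def test_association_requires_calls(repeat_genome):
    genome, rep = repeat_genome
    with pytest.raises(ValueError, match="nothing to test"):
        repeat_association_test([], genome, [rep])


# ---------------------------------------------------------------------------
# element merging


def test_merge_gap_boundaries():
    frags = [("s", 1000, 1200), ("s", 2000, 2100)]  # 800 bp gap -> one
    els, _ = merge_elements(frags, scaffold_lengths={"s": 100_000})
    assert len(els) == 1 and els[0].span_ref == 1100
    frags = [("s", 1000, 1200), ("s", 2800, 2900)]  # 1600 bp gap -> two
    els, _ = merge_elements(frags, scaffold_lengths={"s": 100_000})
    assert len(els) == 2


def test_fragmented_element_merges_to_one():
    frags = [("s", 5000, 5400), ("s", 5600, 5900), ("s", 6300, 6700)]
    els, _ = merge_elements(frags, scaffold_lengths={"s": 100_000})
    assert len(els) == 1
    assert (els[0].start, els[0].end) == (5000, 6700)


def test_oversized_merge_splits_at_largest_gap():
    frags = [("s", 1000, 2400), ("s", 2500, 3900), ("s", 5300, 6000)]
    els, _ = merge_elements(frags, scaffold_lengths={"s": 100_000})
    assert len(els) == 2
    assert els[0].end == 3900 and els[1].start == 5300


def test_edge_element_dropped():
    els, dropped = merge_elements([("s", 200, 900)], scaffold_lengths={"s": 50_000})
    assert els == [] and dropped == 1


# ---------------------------------------------------------------------------
# span comparison


@pytest.fixture(scope="module")
def span_setup():
    rng = np.random.default_rng(70)
    te = random_sequence(1200, rng)
    parts, elements = [], []
    pos = 0
    for _ in range(15):
        # wide spacing: control windows should rarely straddle an element,
        # so that element-specific length jitter stands out against them
        gap = random_sequence(9000, rng)
        parts.append(gap)
        pos += len(gap)
        elements.append(("ref", pos, pos + len(te)))
        parts.append(te)
        pos += len(te)
    parts.append(random_sequence(3000, rng))
    genome = "".join(parts)
    els, _ = merge_elements(elements, scaffold_lengths={"ref": len(genome)})
    return genome, els


def test_spans_null_without_jitter(span_setup):
    genome, els = span_setup
    comp = compare_spans(els, genome, genome, seed=71)
    assert comp.n_elements_measured == len(els)
    assert comp.element_mean_abs_change == 0.0
    assert np.isnan(comp.p_value) or comp.p_value > 0.05


def test_spans_detect_planted_jitter(span_setup):
    genome, els = span_setup
    rng = np.random.default_rng(72)
    # rebuild the sibling with +-50 bp length changes inside each element
    sib = genome
    for el in sorted(els, key=lambda e: -e.start):
        delta = int(rng.integers(30, 70)) * (1 if rng.random() < 0.5 else -1)
        mid = (el.start + el.end) // 2
        if delta > 0:
            sib = sib[:mid] + random_sequence(delta, rng) + sib[mid:]
        else:
            sib = sib[:mid] + sib[mid - delta :]
    comp = compare_spans(els, genome, sib, seed=73)
    assert comp.element_mean_abs_change > comp.control_mean_abs_change
    assert comp.p_value < 0.01


def test_flanks_on_two_contigs_excluded(span_setup):
    genome, els = span_setup
    el = els[0]
    # sibling split between the element's flanks
    cut = (el.start + el.end) // 2
    sibling = {"c1": genome[:cut], "c2": genome[cut:]}
    comp = compare_spans([el], genome, sibling, n_controls=0, seed=74)
    assert comp.n_elements_measured == 0
    assert comp.n_elements_excluded == 1


def test_permutation_p_roughly_uniform_under_null():
    """Over 50 simulated null datasets, rejection at alpha=0.05 happens at
    a rate compatible with 0.05 (within +-0.07)."""
    rng = np.random.default_rng(80)
    rejections = 0
    n_sets = 50
    rep = random_sequence(500, rng)
    for i in range(n_sets):
        parts = []
        for _ in range(4):
            parts.append(random_sequence(int(rng.integers(8000, 16000)), rng))
            parts.append(rep * 6)
        genome = "".join(parts)
        pos = np.sort(rng.choice(len(genome) - 3000, size=20, replace=False) + 1500)
        calls = [DeletionCall("s", int(p), int(p) + 25, 30, 30) for p in pos]
        res = repeat_association_test(calls, genome, [rep], n_perm=200,
                                      seed=int(rng.integers(2**31 - 1)))
        rejections += res.p_value <= 0.05
    assert abs(rejections / n_sets - 0.05) <= 0.07
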