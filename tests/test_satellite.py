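"""Satellite spacing statistics, arrangement classification and abundance."""

import numpy as np
import pytest

from bactrokit._seq import revcomp
from bactrokit.kmers import count_kmers
from bactrokit.satellite import (
    SatelliteModel,
    arrangement_profile,
    estimate_abundance,
    expected_cooccurrence,
    expected_offsets,
    satellite_span_mbp,
)
from bactrokit.simulate import random_sequence, simulate_reads


def brute_cooccurrence(monomer: str, d: int, R: int = 100, k: int = 12) -> float:
    """Enumerate all R bp windows of an explicit tandem array; among windows
    containing an interior anchor occurrence, the fraction that also fully
    contain the k-mer starting d bp from that anchor."""
    arr = monomer * 12
    L = len(monomer)
    anchors = [i * L for i in range(4, 8)]  # interior copies only
    n_with_anchor = n_both = 0
    for s in range(len(arr) - R + 1):
        for a in anchors:
            if s <= a and a + k <= s + R:
                n_with_anchor += 1
                if s <= a + d and a + d + k <= s + R:
                    n_both += 1
    return n_both / n_with_anchor


@pytest.mark.parametrize("d", [0, 12, 24, 50, 70, 88, 89, -22, -82])
def test_expected_cooccurrence_matches_enumeration(monomer, d):
    assert expected_cooccurrence(100, 12, d) == pytest.approx(
        brute_cooccurrence(monomer, d), abs=1e-12
    )


def test_cooccurrence_trivial_values():
    assert expected_cooccurrence(100, 12, 0) == 1.0
    assert expected_cooccurrence(100, 12, 89) == 0.0
    assert round(expected_cooccurrence(100, 12, 12), 2) == 0.87
    with pytest.raises(ValueError):
        expected_cooccurrence(10, 12, 0)


def test_expected_offsets_166(monomer):
    model = SatelliteModel("s", monomer, read_len=100)
    offs = expected_offsets(model)
    assert offs == [-82, -70, -58, -46, -34, -22, 12, 24, 36, 48, 60, 72, 84]
    assert len(offs) == 13


def test_expected_offsets_small_read():
    model = SatelliteModel("s", random_sequence(120, np.random.default_rng(1)),
                           read_len=24)
    # hand enumeration: tile at +12 fits; the tile at 108 wraps across the
    # junction to -12, which a 24 bp read spanning the junction does contain
    assert expected_offsets(model) == [-12, 12]


def test_expected_offsets_long_monomer():
    model = SatelliteModel("s", random_sequence(300, np.random.default_rng(2)),
                           read_len=100)
    offs = expected_offsets(model)
    assert all(0 < abs(d) <= 88 for d in offs)
    # brute-force: enumerate tiling positions and mod-L images
    want = set()
    for p in range(12, 289, 12):
        for d in (p, p - 300):
            if 0 < abs(d) <= 88:
                want.add(d)
    assert set(offs) == want


def test_offsets_match_enumeration_on_tandem_reads(monomer):
    """Observed co-occurrence offsets on error-free tandem reads land
    exactly on the expected offsets, at the expected relative frequency."""
    model = SatelliteModel("s", monomer, read_len=100)
    reads = simulate_reads(monomer * 100, depth=40, read_len=100, seed=3)
    prof = arrangement_profile(reads, model, max_mismatch=0)
    assert prof.classification == "head-to-tail tandem"
    assert prof.fraction_at_expected() == pytest.approx(1.0, abs=1e-9)
    # observed/expected ratio ~ 1 at each offset
    n = prof.n_anchor_reads
    for d, p in prof.expected.items():
        obs = prof.observed.get((d, "+"), 0)
        se = np.sqrt(p * (1 - p) * n)
        assert abs(obs - p * n) <= 4 * max(se, 1.0)


def test_dispersed_monomers_classified_dispersed(monomer):
    rng = np.random.default_rng(4)
    parts = []
    for _ in range(40):
        parts.append(random_sequence(800, rng))
        parts.append(monomer)
    reads = simulate_reads("".join(parts), depth=30, read_len=100, seed=5)
    prof = arrangement_profile(reads, SatelliteModel("s", monomer))
    assert prof.classification == "dispersed"


def test_inverted_dimers_classified_head_to_head(monomer):
    dimer = monomer + revcomp(monomer)
    reads = simulate_reads(dimer * 50, depth=30, read_len=100, seed=6)
    prof = arrangement_profile(reads, SatelliteModel("s", monomer))
    assert prof.classification == "head-to-head"


def test_absent_monomer_not_detected(monomer):
    rng = np.random.default_rng(7)
    reads = simulate_reads(random_sequence(20_000, rng), depth=20, seed=8)
    prof = arrangement_profile(reads, SatelliteModel("s", monomer))
    assert prof.classification == "not detected"


def test_abundance_recovery_and_absence(monomer):
    rng = np.random.default_rng(9)
    genome = (
        random_sequence(30_000, rng) + monomer * 300 + random_sequence(30_000, rng)
    )
    depth = 40
    reads = simulate_reads(genome, depth, read_len=100, error_rate=0.0, seed=10)
    table = count_kmers(reads, 18, "canonical")
    model = SatelliteModel("s", monomer)
    est = estimate_abundance(table, model, depth, 100)
    assert abs(est.canonical - 300) / 300 < 0.10
    assert est.variable >= est.canonical
    absent = SatelliteModel("none", random_sequence(166, rng))
    est0 = estimate_abundance(table, absent, depth, 100)
    assert est0.canonical == 0.0


def test_abundance_counts_single_substitution_variants(monomer):
    variant = list(monomer)
    variant[40] = "A" if monomer[40] != "A" else "G"
    variant = "".join(variant)
    rng = np.random.default_rng(11)
    genome = (
        random_sequence(20_000, rng) + monomer * 200 + variant * 100
        + random_sequence(20_000, rng)
    )
    depth = 40
    reads = simulate_reads(genome, depth, read_len=100, seed=12)
    table = count_kmers(reads, 18, "canonical")
    est = estimate_abundance(table, SatelliteModel("s", monomer), depth, 100)
    # canonical misses the variant copies at the mutated tile only, so the
    # canonical mean sits between 200 and 300; variable recovers all 300
    assert abs(est.variable - 300) / 300 < 0.10


def test_abundance_depth_invariant(monomer):
    rng = np.random.default_rng(13)
    genome = random_sequence(20_000, rng) + monomer * 200 + random_sequence(20_000, rng)
    ests = []
    for depth, seed in ((20, 14), (40, 15)):
        reads = simulate_reads(genome, depth, read_len=100, seed=seed)
        table = count_kmers(reads, 18, "canonical")
        ests.append(estimate_abundance(table, SatelliteModel("s", monomer), depth, 100).canonical)
    assert abs(ests[0] - ests[1]) / ests[1] < 0.05


def test_span_arithmetic():
    assert satellite_span_mbp(166, 250_000) == pytest.approx(41.5)
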