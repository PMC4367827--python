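"""Greedy k-mer extension vs an independent brute-force oracle, the
align-and-extend consensus builder, finalization and variant libraries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bactrokit._seq import min_rotation, revcomp
from bactrokit.kmers import count_kmers
from bactrokit.repeats import (
    RepeatConsensus,
    align_and_extend,
    cull_redundant,
    finalize_consensus,
    kmer_extend,
    pairwise_identity,
    species_specific_variants,
)
from bactrokit.simulate import ReadSet, random_sequence, simulate_reads


# ---------------------------------------------------------------------------
# oracle: hash-scan greedy walk over a string-keyed count dict


def oracle_extend(counts, top_n, min_extension=50, min_count=2,
                  stop_ratio=0.2, max_len=10000):
    k = len(next(iter(counts)))
    consumed = set()
    out = []
    seeds = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]

    def best(cands):
        return sorted(cands, key=lambda kv: (-kv[1], kv[0]))[0] if cands else None

    for seed, scount in seeds:
        if seed in consumed or scount < min_count:
            continue
        consumed.add(seed)
        seq, circular, peak = seed, False, scount
        while len(seq) < max_len:
            suffix = seq[-(k - 1):]
            cand = best([(w, c) for w, c in counts.items()
                         if w[: k - 1] == suffix and c >= min_count])
            if cand is None or cand[1] < stop_ratio * peak:
                break
            if cand[0] in consumed:
                circular = cand[0] == seed
                break
            consumed.add(cand[0])
            seq += cand[0][-1]
            peak = max(peak, cand[1])
        peak = scount
        while len(seq) < max_len:
            prefix = seq[: k - 1]
            cand = best([(w, c) for w, c in counts.items()
                         if w[1:] == prefix and c >= min_count])
            if cand is None or cand[1] < stop_ratio * peak:
                break
            if cand[0] in consumed:
                break
            consumed.add(cand[0])
            seq = cand[0][0] + seq
            peak = max(peak, cand[1])
        if len(seq) < k + min_extension:
            continue
        if circular:
            seq = min_rotation(seq[: len(seq) - (k - 1)])
        out.append((seq, circular))
    return out


def _run_both(seqs, k, top_n=100, **kw):
    table = count_kmers([(str(i), s) for i, s in enumerate(seqs)], k, "as-read")
    got = [(r.sequence, r.circular) for r in kmer_extend(table, top_n=top_n, **kw)]
    want = oracle_extend(table.as_dict(), top_n, **kw)
    return got, want


dna = st.text(alphabet="ACGT", min_size=10, max_size=80)


@settings(max_examples=40, deadline=None)
@given(st.lists(dna, min_size=1, max_size=5), st.integers(4, 7))
def test_extension_matches_oracle(seqs, k):
    got, want = _run_both(seqs, k, min_extension=3)
    assert got == want


def test_unique_high_count_region_reproduced_exactly():
    """A 200-mer tiled at count 100 against count-1 background reproduces
    the 200-mer as a single extension."""
    rng = np.random.default_rng(1)
    core = random_sequence(200, rng)
    reads = [core] * 100  # every 18-mer of the core at count exactly 100
    noise = [random_sequence(30, rng) for _ in range(50)]
    table = count_kmers([(str(i), s) for i, s in enumerate(reads + noise)], 18, "as-read")
    lib = kmer_extend(table, top_n=5000, min_extension=50)
    assert any(r.sequence == core for r in lib)


def test_tandem_monomer_closes_circular(monomer):
    """Reads over a tandem array halt when the walk revisits its seed; the
    monomer comes back in minimal rotation."""
    reads = simulate_reads(monomer * 80, depth=20, read_len=100, seed=2)
    table = count_kmers(reads, 18, "as-read")
    lib = kmer_extend(table, top_n=500)
    circ = [r for r in lib if r.circular]
    assert circ
    assert circ[0].sequence == min_rotation(monomer) or circ[0].sequence == min_rotation(revcomp(monomer))
    assert len(circ[0].sequence) == 166


def test_equal_counts_tie_lexicographic():
    got, want = _run_both(["ACGTACGTAA"], 4, min_extension=2)
    assert got == want
    # rerun gives the identical, deterministic output
    assert got == _run_both(["ACGTACGTAA"], 4, min_extension=2)[0]


def test_no_kmer_consumed_twice():
    seqs = [random_sequence(60, np.random.default_rng(3)) for _ in range(4)] * 3
    table = count_kmers([(str(i), s) for i, s in enumerate(seqs)], 6, "as-read")
    lib = kmer_extend(table, top_n=1000, min_extension=3, min_count=1)
    seen = set()
    for r in lib:
        for i in range(len(r.sequence) - 5):
            w = r.sequence[i : i + 6]
            # circular monomers are rotated, skip those
            if not r.circular:
                assert w not in seen
                seen.add(w)


# ---------------------------------------------------------------------------
# align-and-extend


@pytest.fixture(scope="module")
def element_genome():
    rng = np.random.default_rng(9)
    element = random_sequence(700, rng)
    parts = []
    for _ in range(50):
        parts.append(random_sequence(300, rng))
        parts.append(element)
    parts.append(random_sequence(300, rng))
    return element, "".join(parts)


def test_align_and_extend_recovers_full_element(element_genome):
    element, genome = element_genome
    seed = RepeatConsensus("seed", element[200:500])
    out = align_and_extend(seed, genome, flank=200)
    assert element in out.sequence
    # extension stops near the element boundary (flanks disagree)
    assert len(out.sequence) <= len(element) + 30


def test_single_copy_seed_returned_unchanged():
    rng = np.random.default_rng(10)
    element = random_sequence(400, rng)
    genome = random_sequence(2000, rng) + element + random_sequence(2000, rng)
    seed = RepeatConsensus("s", element[100:300])
    out = align_and_extend(seed, genome)
    assert out.sequence == element[100:300]
    assert out.support["n_matches"] == 1


def test_divergent_flanks_block_extension():
    rng = np.random.default_rng(11)
    core = random_sequence(300, rng)
    parts = []
    for _ in range(20):
        parts.append(random_sequence(200, rng))  # ~50% column agreement
        parts.append(core)
    genome = "".join(parts) + random_sequence(200, rng)
    out = align_and_extend(RepeatConsensus("s", core), genome)
    assert len(out.sequence) <= len(core) + 10


def test_zero_matches_warns():
    rng = np.random.default_rng(12)
    seed = RepeatConsensus("s", random_sequence(100, rng))
    with pytest.warns(UserWarning, match="no assembly matches"):
        out = align_and_extend(seed, random_sequence(5000, rng))
    assert out.sequence == seed.sequence


# ---------------------------------------------------------------------------
# finalization, culling, species variants


def test_duplicate_entries_culled_keeping_longer():
    rng = np.random.default_rng(13)
    seq = random_sequence(300, rng)
    lib = [RepeatConsensus("long", seq + "ACGT"), RepeatConsensus("dup", seq)]
    kept = cull_redundant(lib)
    assert [r.id for r in kept] == ["long"]


def test_revcomp_duplicate_culled():
    rng = np.random.default_rng(14)
    seq = random_sequence(250, rng)
    kept = cull_redundant(
        [RepeatConsensus("a", seq), RepeatConsensus("b", revcomp(seq))]
    )
    assert len(kept) == 1


def test_distinct_entries_survive_culling():
    rng = np.random.default_rng(15)
    lib = [RepeatConsensus(f"r{i}", random_sequence(200, rng)) for i in range(4)]
    kept = cull_redundant(lib)
    assert len(kept) == 4
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            assert pairwise_identity(a.sequence, b.sequence) <= 0.80


def test_majority_snp_installed():
    """A consistent 90%-frequency variant in the reads replaces the draft
    consensus base."""
    rng = np.random.default_rng(16)
    true_seq = random_sequence(400, rng)
    draft = list(true_seq)
    draft[200] = "A" if true_seq[200] != "A" else "C"  # wrong draft base
    reads = simulate_reads(true_seq, depth=30, read_len=100, seed=17)
    lib, stats = finalize_consensus([RepeatConsensus("x", "".join(draft))], reads)
    assert lib[0].sequence == true_seq


def test_mapped_fraction_tracks_repetitive_content(small_genome, small_reads, monomer, transposon_seq):
    truth = small_genome["truth"]
    lib = [
        RepeatConsensus("sat", monomer, circular=True),
        RepeatConsensus("te", transposon_seq),
    ]
    _lib, stats = finalize_consensus(lib, small_reads)
    # a read maps if it lies inside a planted repeat or overlaps one enough
    # to anchor (soft-clipped boundary reads), so the mapped fraction falls
    # between the fully-inside and any-overlap geometric expectations
    R = small_reads.read_len
    rep_feats = [f for f in truth.features if f.type in ("satellite", "transposon")]
    lower = sum(max(0, (f.end - f.start) - R) for f in rep_feats)
    upper = sum((f.end - f.start) + R for f in rep_feats)
    G = len(small_genome["genome"])
    assert lower / G - 0.01 <= stats["mapped_read_fraction"] <= upper / G + 0.01


def test_species_variants_identity_when_same_reads():
    rng = np.random.default_rng(18)
    seq = random_sequence(500, rng)
    reads = simulate_reads(seq, depth=25, read_len=100, seed=19)
    out = species_specific_variants([RepeatConsensus("x", seq)], reads)
    assert out[0].sequence == seq
    assert out[0].id == "x|sibling"


def test_species_variants_recover_divergent_monomer(monomer):
    variant = list(monomer)
    variant[30] = "A" if monomer[30] != "A" else "T"
    variant[120] = "G" if monomer[120] != "G" else "C"
    variant = "".join(variant)
    sib_reads = simulate_reads(variant * 60, depth=30, read_len=100, seed=20)
    out = species_specific_variants(
        [RepeatConsensus("sat", monomer, circular=True)], sib_reads
    )
    assert out[0].sequence == variant


def test_species_variants_zero_coverage_flagged(monomer):
    rng = np.random.default_rng(21)
    other = random_sequence(3000, rng)
    reads = simulate_reads(other, depth=20, read_len=100, seed=22)
    out = species_specific_variants([RepeatConsensus("sat", monomer)], reads)
    assert out[0].support.get("zero_coverage")
    assert out[0].sequence == monomer


def test_exact_half_frequency_not_substituted():
    """An allele at exactly 50% stays (strict > rule)."""
    rng = np.random.default_rng(23)
    seq = random_sequence(300, rng)
    alt = list(seq)
    alt[150] = "A" if seq[150] != "A" else "C"
    alt = "".join(alt)
    ids, seqs = [], []
    for i in range(10):
        src = seq if i % 2 == 0 else alt
        ids.append(f"r{i}")
        seqs.append(src[100:200])
    reads = ReadSet(ids=ids, seqs=seqs, read_len=100)
    out = species_specific_variants([RepeatConsensus("x", seq)], reads)
    assert out[0].sequence == seq
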