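"""Fixed-difference calling, region partitioning, codon effects (exhaustive
oracle), and rRNA variant profiling."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from bactrokit.divergence import (
    CdsExon,
    CdsModel,
    GENETIC_CODE,
    STOP_CODONS,
    VariantCall,
    call_fixed_differences,
    cds_models_from_truth,
    classify_coding_effect,
    partition_by_region,
    rrna_variant_profile,
)
from bactrokit.mapping import Alignment, map_reads
from bactrokit.pileup import Pileup, pileup_from_alignments
from bactrokit.simulate import (
    REGION_CODES,
    SiblingSpec,
    derive_sibling,
    mutate_sequence,
    random_sequence,
    simulate_reads,
)


def _pile(ref_len, base_cols):
    """Pileup from {pos: {base: count}}."""
    pile = Pileup({"ref": ref_len})
    for pos, col in base_cols.items():
        for base, cnt in col.items():
            pile.counts["ref"]["ACGT".index(base), pos] = cnt
    return pile


def test_genetic_code_matches_biopython():
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        assert GENETIC_CODE[codon] == str(Seq(codon).translate())


def test_call_thresholds():
    ref = {"ref": "A" * 100}
    pile = _pile(100, {10: {"A": 1, "G": 39}, 20: {"G": 9}, 30: {"A": 5, "G": 5}})
    calls = call_fixed_differences(pile, ref)
    assert [(c.pos, c.alt) for c in calls] == [(10, "G")]
    assert calls[0].depth == 40 and calls[0].freq == pytest.approx(39 / 40)


def test_empty_pileup_no_calls():
    assert call_fixed_differences(Pileup({"ref": 50}), {"ref": "A" * 50}) == []


# ---------------------------------------------------------------------------
# coding effects: exhaustive oracle over all codon pairs


def oracle_effect(ref_codon, alt_codon):
    """Classify a ref->alt codon change via independent translation."""
    subs = [(i, b) for i, (a, b) in enumerate(zip(ref_codon, alt_codon)) if a != b]
    if str(Seq(alt_codon).translate()) == "*":
        return "stop_gain"
    for i, b in subs:
        single = ref_codon[:i] + b + ref_codon[i + 1 :]
        if str(Seq(single).translate()) == "*":
            return "stop_compensated"
    if str(Seq(alt_codon).translate()) == str(Seq(ref_codon).translate()):
        return "synonymous"
    return "nonsynonymous"


def test_effect_matches_oracle_on_all_codon_pairs():
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    n_comp = 0
    for ref in codons:
        if ref in STOP_CODONS:
            continue
        for alt in codons:
            if alt == ref:
                continue
            subs = [(i, b) for i, (a, b) in enumerate(zip(ref, alt)) if a != b]
            got = classify_coding_effect(ref, subs)
            assert got == oracle_effect(ref, alt), (ref, alt)
            n_comp += got == "stop_compensated"
    assert n_comp > 0  # compensated-stop logic actually exercised


def test_effect_examples():
    assert classify_coding_effect("CAA", [(0, "T")]) == "stop_gain"
    # CAA -> TAC: TAA as an intermediate is negated by the second change
    assert classify_coding_effect("CAA", [(0, "T"), (2, "C")]) == "stop_compensated"
    assert classify_coding_effect("GCT", [(2, "C")]) == "synonymous"


def test_phase_inconsistency_raises():
    seq = "A" * 100
    with pytest.raises(ValueError, match="phase"):
        CdsModel("g", [CdsExon(0, 10, 0), CdsExon(20, 30, 0)], seq)


# ---------------------------------------------------------------------------
# region partitioning


def test_partition_counts_and_denominators():
    ref_len = 300
    region = np.zeros(ref_len, dtype=np.uint8)
    region[0:100] = REGION_CODES["exon"]
    region[100:200] = REGION_CODES["intron"]
    cols = {p: {"A": 30} for p in range(0, 300, 2)}  # callable every 2nd site
    cols[10] = {"G": 30}
    cols[150] = {"G": 30}
    cols[250] = {"G": 30}
    pile = _pile(ref_len, cols)
    calls = call_fixed_differences(pile, {"ref": "A" * ref_len})
    part = partition_by_region(calls, {"ref": region}, pile)
    assert part.counts == {"exon": 1, "intron": 1, "noncoding": 1, "utr5": 0, "utr3": 0}
    assert sum(part.callable_sites.values()) == 150
    assert part.rates["exon"] == pytest.approx(1 / 50)


def test_region_partition_recovers_planted_rates(small_genome):
    """Sibling at (exon .003, intron .006, noncoding .007): recovered counts
    within 3 binomial s.d. and rate ordering preserved."""
    genome, truth = small_genome["genome"], small_genome["truth"]
    rates = {"exon": 0.003, "intron": 0.006, "noncoding": 0.007}
    sib, st = derive_sibling(genome, truth, SiblingSpec(
        substitution_rate_by_region=rates, seed=31))
    reads = simulate_reads(sib, 30, 100, error_rate=0.0, seed=32)
    alns = map_reads(reads, genome)
    pile = pileup_from_alignments(alns, {"ref": len(genome)})
    calls = call_fixed_differences(pile, {"ref": genome})
    region = {"ref": truth.region_array()}
    part = partition_by_region(calls, region, pile,
                               {"ref": cds_models_from_truth(truth, genome)})
    # repeat-region substitutions are uncallable (ambiguous mapping), so the
    # comparison is per callable site: observed count vs rate x callable
    for name, rate in rates.items():
        callable_n = part.callable_sites[name]
        expect = rate * callable_n
        sd = np.sqrt(callable_n * rate * (1 - rate))
        assert abs(part.counts[name] - expect) <= 3 * sd + 1, name
    assert part.rates["intron"] > part.rates["exon"]
    assert part.rates["noncoding"] > part.rates["exon"]


def test_zero_rate_sibling_zero_calls(small_genome):
    genome, truth = small_genome["genome"], small_genome["truth"]
    reads = simulate_reads(genome, 25, 100, error_rate=0.0, seed=33)
    alns = map_reads(reads, genome)
    pile = pileup_from_alignments(alns, {"ref": len(genome)})
    calls = call_fixed_differences(pile, {"ref": genome})
    part = partition_by_region(calls, {"ref": truth.region_array()}, pile)
    assert all(v == 0 for v in part.counts.values())


# ---------------------------------------------------------------------------
# rRNA profiling


def _unit_pileup(copies, consensus, seed):
    # copies are pooled tandem, as in a real rDNA locus; junction-spanning
    # reads cannot be soft-clipped by the internal mapper, so they are
    # removed by the NM ceiling instead
    reads = simulate_reads("".join(copies), depth=30, read_len=100, seed=seed)
    alns = map_reads(reads, {"rrna": consensus}, max_candidates=8, max_mismatches=8)
    return pileup_from_alignments(alns, {"rrna": len(consensus)}, min_q=-1)


def test_error_free_single_haplotype_profile_is_zero():
    rng = np.random.default_rng(41)
    unit = random_sequence(2000, rng)
    pile = _unit_pileup([unit] * 5, unit, 42)
    df = rrna_variant_profile(pile, unit)
    covered = df.dropna(subset=["variant_fraction"])
    assert (covered.variant_fraction == 0).all()


def test_divergent_its_copies_elevate_its_windows_only():
    rng = np.random.default_rng(43)
    unit = random_sequence(3000, rng)
    its = (1000, 1500)
    mask = np.zeros(3000, dtype=bool)
    mask[its[0] : its[1]] = True
    divergent, _pos = mutate_sequence(unit, 0.05, rng, mask)
    copies = [unit] * 16 + [divergent] * 4  # 20% of copies carry ITS variants
    pile = _unit_pileup(copies, unit, 44)
    df = rrna_variant_profile(
        pile, unit, regions=[("ITS1", its[0], its[1]), ("18S", 0, its[0])]
    )
    by_region = df.groupby("region")["variant_fraction"].mean()
    assert by_region["ITS1"] > 5 * max(by_region["18S"], 1e-6)


def test_two_pools_recover_planted_heterogeneity_ratio():
    rng = np.random.default_rng(45)
    unit = random_sequence(2500, rng)
    pools = {}
    for name, rate in (("a", 0.02), ("b", 0.01)):
        div, _ = mutate_sequence(unit, rate, rng)
        pools[name] = [unit] * 10 + [div] * 10
    fracs = {}
    for i, (name, copies) in enumerate(pools.items()):
        pile = _unit_pileup(copies, unit, 46 + i)
        df = rrna_variant_profile(pile, unit)
        fracs[name] = df.variant_fraction.mean()
    assert fracs["a"] / fracs["b"] == pytest.approx(2.0, rel=0.35)


def test_dn_ds_counts_match_expectation_under_no_selection():
    """Uniform random single-base codon changes: the synonymous fraction
    matches the genetic code's mean synonymous-site opportunity."""
    from bactrokit.divergence import _synonymous_site_fraction

    rng = np.random.default_rng(47)
    codons = [c for c in GENETIC_CODE if c not in {"TAA", "TAG", "TGA"}]
    n = 4000
    syn = 0
    weights = []
    for _ in range(n):
        ref = codons[int(rng.integers(len(codons)))]
        off = int(rng.integers(3))
        alt = "ACGT".replace(ref[off], "")[int(rng.integers(3))]
        effect = classify_coding_effect(ref, [(off, alt)])
        syn += effect == "synonymous"
    expect = float(np.mean([_synonymous_site_fraction(c) for c in codons]))
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(syn / n - expect) < 4 * se + 0.01
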