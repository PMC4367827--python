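"""End-to-end pipeline on synthetic data: simulate -> count k-mers ->
discover repeats -> satellite statistics -> genome size (two estimators)
-> sibling divergence -> deletions -> association -> element spans.

Every stage consumes only the outputs of earlier stages plus the
configuration; the truth set is used solely to *score* callers (recall,
precision, realized rates), never to produce their inputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import divergence as dv
from . import genomesize as gs
from . import kmers, repeats, satellite, seqio, structural
from .config import PipelineConfig
from .mapping import ReferenceIndex, map_reads
from .pileup import CoverageTrack, pileup_from_alignments
from .simulate import (
    GeneSpec,
    GenomeSpec,
    SatelliteArraySpec,
    SiblingSpec,
    TransposonSpec,
    build_genome,
    derive_sibling,
    random_monomer,
    random_sequence,
    simulate_reads,
)

log = logging.getLogger("bactrokit")


def default_genome_spec(cfg: PipelineConfig) -> GenomeSpec:
    rng = np.random.default_rng(cfg.stage_seed("genome") + 555)
    sats = [
        SatelliteArraySpec(monomer=random_monomer(L, rng), copies=c, arrays=1)
        for L, c in zip(cfg.genome.satellite_monomer_lengths, cfg.genome.satellite_copies)
    ]
    tn = TransposonSpec(
        sequence=random_sequence(cfg.genome.transposon_length, rng),
        n_insertions=cfg.genome.transposon_insertions,
        fragmentation_rate=cfg.genome.transposon_fragmentation,
    )
    genes = GeneSpec(count=cfg.genome.n_genes, length_range=cfg.genome.gene_length_range)
    return GenomeSpec(
        length=cfg.genome.length, satellites=sats, transposon=tn, genes=genes,
        seed=cfg.stage_seed("genome"),
    )


def sibling_spec(cfg: PipelineConfig) -> SiblingSpec:
    return SiblingSpec(
        substitution_rate_by_region={
            "exon": cfg.sibling.rate_exon,
            "intron": cfg.sibling.rate_intron,
            "utr5": cfg.sibling.rate_utr5,
            "utr3": cfg.sibling.rate_utr3,
            "noncoding": cfg.sibling.rate_noncoding,
        },
        n_random_deletions=cfg.sibling.n_deletions,
        deletion_length_range=cfg.sibling.deletion_length_range,
        transposon_jitter_sd=cfg.sibling.transposon_jitter_sd,
        seed=cfg.stage_seed("sibling"),
    )


def score_deletions(calls, truth, slack: int = 6) -> dict:
    """Precision/recall of deletion calls against planted truth.

    Boundaries are matched with ``slack`` bp of tolerance: micro-homology
    at a breakpoint shifts the zero-coverage run by a few bases in a way
    no read-level evidence can resolve."""
    planted = list(truth.deletions)
    matched = set()
    tp = 0
    for c in calls:
        hit = None
        for i, (s, ln) in enumerate(planted):
            if i in matched:
                continue
            if abs(c.start - s) <= slack and abs(c.length - ln) <= 2 * slack:
                hit = i
                break
        if hit is not None:
            matched.add(hit)
            tp += 1
    n_calls = len(calls)
    n_true = len(planted)
    return {
        "true_positives": tp,
        "n_calls": n_calls,
        "n_planted": n_true,
        "precision": tp / n_calls if n_calls else float("nan"),
        "recall": tp / n_true if n_true else float("nan"),
    }


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
    return_state: bool = False,
):
    """Run every stage; returns the report dict (also written to
    ``outdir/report.json`` with FASTA/TSV side files when ``outdir`` given).
    With ``return_state`` the in-memory objects (genome, truth sets, library,
    calls, partitions) are returned alongside for downstream scoring."""
    report: dict = {"config_seed": cfg.seed}
    t0 = time.time()

    def stage(name: str) -> None:
        log.info("stage %-18s t=%.1fs", name, time.time() - t0)

    stage("simulate")
    gspec = default_genome_spec(cfg)
    genome, truth = build_genome(gspec)
    sibling, sib_truth = derive_sibling(genome, truth, sibling_spec(cfg))
    reads = simulate_reads(
        genome, cfg.reads.depth, cfg.reads.read_len, cfg.reads.error_rate,
        paired=cfg.reads.paired, insert_mean=cfg.reads.insert_mean,
        insert_sd=cfg.reads.insert_sd, seed=cfg.stage_seed("reads"),
    )
    sib_reads = simulate_reads(
        sibling, cfg.reads.depth_sibling, cfg.reads.read_len, cfg.reads.error_rate,
        paired=cfg.reads.paired, insert_mean=cfg.reads.insert_mean,
        insert_sd=cfg.reads.insert_sd, seed=cfg.stage_seed("sibling_reads"),
    )
    report["genome_length"] = len(genome)
    report["n_reads"] = len(reads)

    stage("kmer-size")
    table_canon = kmers.count_kmers(reads, cfg.kmer.k_discovery, "canonical")
    try:
        kmer_size = kmers.genome_size_from_histogram(table_canon.histogram())
    except kmers.CoverageTooLow:
        kmer_size = float("nan")
    report["kmer_genome_size_bp"] = kmer_size

    stage("repeat-discovery")
    table_asread = kmers.count_kmers(reads, cfg.kmer.k_discovery, "as-read")
    lib = repeats.kmer_extend(
        table_asread, top_n=cfg.kmer.top_n_seeds, min_extension=cfg.kmer.min_extension,
        min_count=cfg.kmer.min_count, stop_ratio=cfg.kmer.stop_ratio,
        max_len=cfg.kmer.max_walk_len,
    )
    del table_asread
    report["n_extension_sequences"] = len(lib)
    # align-and-extend the abundant, element-sized entries against the genome
    refined = []
    depth = cfg.reads.depth
    for entry in lib:
        if entry.circular or not (200 <= len(entry.sequence) <= 3000):
            refined.append(entry)
            continue
        if entry.support.get("seed_count", 0) < 3 * depth:
            refined.append(entry)
            continue
        refined.append(
            repeats.align_and_extend(
                entry, genome, flank=cfg.repeats.align_flank,
                consensus_threshold=cfg.repeats.consensus_threshold,
                min_identity=cfg.repeats.min_identity,
                min_support=cfg.repeats.min_support,
            )
        )
    compact = [r for r in refined if len(r.sequence) <= 2 * cfg.elements.canonical_len]
    # copy-number filter: an extension walk through single-copy sequence is
    # not a repeat; keep entries with >= 2 genomic fragments (or circular)
    idx12 = ReferenceIndex({"ref": genome}, seed_len=12)
    multi = []
    for r in compact:
        if r.circular:
            r.support["n_fragments"] = None
            multi.append(r)
            continue
        n_frag = len(
            repeats.find_fragments(r.sequence, idx12, cfg.repeats.min_identity,
                                   cfg.association.min_hit_len)
        )
        r.support["n_fragments"] = n_frag
        if n_frag >= 2:
            multi.append(r)
    if multi:
        final_lib, lib_stats = repeats.finalize_consensus(
            multi, reads, min_q=cfg.mapping.q_general,
            max_identity=cfg.repeats.max_library_identity,
        )
    else:
        final_lib, lib_stats = [], {}
    report["repeat_library"] = {
        "n_entries": len(final_lib),
        "n_single_copy_discarded": len(compact) - len(multi),
        "lengths": sorted(len(r.sequence) for r in final_lib),
        **{k: v for k, v in lib_stats.items()},
    }

    stage("satellite")
    sat_report = []
    per_base_depth = cfg.reads.depth
    for entry in final_lib:
        if not entry.circular or not 100 <= len(entry.sequence) <= 300:
            continue
        model = satellite.SatelliteModel(entry.id, entry.sequence, cfg.reads.read_len)
        prof = satellite.arrangement_profile(reads, model)
        ab = satellite.estimate_abundance(table_canon, model, per_base_depth,
                                          cfg.reads.read_len)
        sat_report.append(
            {"id": entry.id, "monomer_len": model.length,
             "classification": prof.classification,
             "fraction_at_expected": prof.fraction_at_expected(),
             "canonical_copies": ab.canonical, "variable_copies": ab.variable,
             "total_span_mbp": ab.total_span_mbp}
        )
    report["satellites"] = sat_report
    del table_canon

    stage("genome-size")
    segments = gs.segments_from_truth(genome, truth, flank=cfg.genome_size.segment_flank)
    try:
        retained = gs.coverage_filter_cascade(
            segments, reads, low=cfg.genome_size.coverage_low,
            high=cfg.genome_size.coverage_high,
            q_initial=cfg.mapping.q_transcript_initial,
            q_final=cfg.mapping.q_unique, aed_max=cfg.genome_size.aed_max,
        )
        est = gs.estimate_genome_size(retained, len(reads) * cfg.reads.read_len)
        report["coverage_genome_size"] = {
            "peak_coverage": est.peak_coverage,
            "size_bp": est.size_bp,
            "retained_segments": est.retained_segments,
        }
    except (gs.InsufficientSegments, gs.AmbiguousPeak) as exc:
        report["coverage_genome_size"] = {"error": str(exc)}

    stage("divergence")
    ref_index = ReferenceIndex({"ref": genome}, seed_len=cfg.mapping.seed_len)
    sib_alignments = map_reads(sib_reads, ref_index)
    pile = pileup_from_alignments(sib_alignments, {"ref": len(genome)},
                                  min_q=cfg.mapping.q_general)
    calls = dv.call_fixed_differences(
        pile, {"ref": genome}, min_depth=cfg.variants.min_depth,
        homozygous_freq=cfg.variants.homozygous_freq,
    )
    region = {"ref": truth.region_array()}
    cds = {"ref": dv.cds_models_from_truth(truth, genome)}
    part = dv.partition_by_region(calls, region, pile, cds,
                                  min_depth=cfg.variants.min_depth)
    report["divergence"] = {
        "n_calls": len(calls),
        "rates": part.rates,
        "truth_counts": sib_truth.region_edit_counts,
        "dn_rate": part.dn_rate, "ds_rate": part.ds_rate,
        "dnds_raw": part.dnds_raw,
        "dnds_site_normalized": part.dnds_site_normalized,
        "novel_stops": part.novel_stops,
        "compensated_stops": part.compensated_stops,
    }

    stage("deletions")
    track = CoverageTrack.from_alignments(
        sib_alignments, {"ref": len(genome)}, min_q=cfg.mapping.q_general,
        paired_only=cfg.reads.paired,
    )
    dels, del_stats = structural.find_deletions(
        track, min_len=cfg.deletions.min_len, flank_len=cfg.deletions.flank_len,
        flank_min_cov=cfg.deletions.flank_min_cov,
        noise_cov=cfg.deletions.noise_cov, noise_len=cfg.deletions.noise_len,
    )
    report["deletions"] = {**del_stats, **score_deletions(dels, sib_truth)}

    stage("association")
    if dels and final_lib:
        assoc = structural.repeat_association_test(
            dels, genome, [r.sequence for r in final_lib],
            n_perm=cfg.association.n_permutations,
            identity=cfg.association.identity,
            min_hit=cfg.association.min_hit_len,
            flank=cfg.association.flank,
            seed=cfg.stage_seed("association"),
        )
        report["association"] = {
            "observed_fraction": assoc.observed_fraction,
            "null_mean": assoc.null_mean, "p_value": assoc.p_value,
        }
    else:
        report["association"] = {"skipped": "no deletions or empty library"}

    stage("spans")
    te_entries = [
        r for r in final_lib
        if not r.circular and 500 <= len(r.sequence) <= 2 * cfg.elements.canonical_len
    ]
    frags = []
    if te_entries:
        # the canonical dispersed element = the entry with the most genomic
        # fragments
        scored = [
            (len(repeats.find_fragments(r.sequence, idx12, cfg.repeats.min_identity,
                                        cfg.association.min_hit_len)), r)
            for r in te_entries
        ]
        n_hits, canonical = max(scored, key=lambda t: t[0])
        te_entries = [canonical] if n_hits >= 3 else []
    if te_entries:
        frags = [
            ("ref", s, e)
            for s, e in repeats.find_fragments(canonical.sequence, idx12,
                                               cfg.repeats.min_identity,
                                               cfg.association.min_hit_len)
        ]
        els, dropped = structural.merge_elements(
            frags, merge_dist=cfg.elements.merge_dist,
            canonical_len=cfg.elements.canonical_len, flank=cfg.elements.flank,
            scaffold_lengths={"ref": len(genome)},
        )
        comp = structural.compare_spans(
            els, genome, sibling, flank=cfg.elements.flank,
            seed=cfg.stage_seed("spans"),
        )
        report["spans"] = {
            "n_elements": len(els), "n_measured": comp.n_elements_measured,
            "element_mean_abs_change": comp.element_mean_abs_change,
            "control_mean_abs_change": comp.control_mean_abs_change,
            "p_value": comp.p_value,
        }
    else:
        report["spans"] = {"skipped": "no element-sized repeat consensus"}

    stage("done")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(outdir / "reference.fa", {"ref": genome})
        seqio.write_fasta(outdir / "sibling.fa", {"sibling": sibling})
        seqio.write_fasta(
            outdir / "repeat_library.fa",
            {f"{r.id}|{r.class_label}|{len(r.sequence)}": r.sequence for r in final_lib},
        )
        truth.to_json(outdir / "truth.json")
        sib_truth.to_json(outdir / "sibling_truth.json")
        seqio.write_gff3(outdir / "genes.gff3", seqio.truth_to_gff3(truth))
        if dels:
            seqio.write_bed(outdir / "deletions.bed", structural.deletions_to_bed(dels))
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    if return_state:
        state = {
            "genome": genome, "truth": truth, "sibling": sibling,
            "sib_truth": sib_truth, "library": final_lib, "calls": calls,
            "partition": part, "deletion_calls": dels, "reads": reads,
        }
        return report, state
    return report
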