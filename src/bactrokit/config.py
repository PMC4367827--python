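"""Pipeline configuration: every tunable threshold, keyed and documented,
with YAML round-tripping.  Unknown keys are rejected.

Defaults follow the study conditions the package emulates: 18-mers for
discovery and abundance, 12-mers for spacing, mapping-quality floors of 20
(general), 30 (initial transcript mapping) and 55 (unique mapping), a depth
floor of 10 for variant calls, zero-coverage deletion calling with 10-base
flanks above 20x, 1000 permutations for the association test, and 1.5 kb
merge distance for fragmented transposon elements.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeConfig(_Section):
    length: int = 2_000_000
    satellite_monomer_lengths: list[int] = [166, 178]
    satellite_copies: list[int] = [500, 200]
    transposon_length: int = 1500
    transposon_insertions: int = 40
    transposon_fragmentation: float = 0.5
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (900, 1500)


class ReadConfig(_Section):
    depth: float = 35.0
    # sibling resequencing is simulated deeper: the zero-coverage deletion
    # screen needs flank depth well above the 20x floor even at the
    # breakpoint-adjacent bases, where only reads anchored on that side count
    depth_sibling: float = 70.0
    read_len: int = 100
    error_rate: float = 0.005
    paired: bool = True
    insert_mean: int = 300
    insert_sd: int = 30


class SiblingConfig(_Section):
    # per-region substitution rates, mirroring the observed ordering
    # (coding most constrained, non-coding least)
    rate_exon: float = 0.003
    rate_intron: float = 0.006
    rate_utr5: float = 0.0036
    rate_utr3: float = 0.0026
    rate_noncoding: float = 0.007
    n_deletions: int = 30
    deletion_length_range: tuple[int, int] = (15, 80)
    transposon_jitter_sd: float = 50.0


class KmerConfig(_Section):
    k_discovery: int = 18
    k_arrange: int = 12
    top_n_seeds: int = 50000
    min_extension: int = 50
    min_count: int = 2
    stop_ratio: float = 0.2
    max_walk_len: int = 10000


class MappingConfig(_Section):
    seed_len: int = 19
    q_general: int = 20
    q_transcript_initial: int = 29
    q_unique: int = 55


class GenomeSizeConfig(_Section):
    coverage_low: float = 10.0
    coverage_high: float = 60.0
    aed_max: float = 0.2
    segment_flank: int = 100


class RepeatConfig(_Section):
    align_flank: int = 200
    consensus_threshold: float = 0.60
    min_identity: float = 0.80
    min_support: int = 3
    max_library_identity: float = 0.80
    variant_min_freq: float = 0.5


class VariantConfig(_Section):
    min_depth: int = 10
    homozygous_freq: float = 0.9


class DeletionConfig(_Section):
    min_len: int = 10
    flank_len: int = 10
    flank_min_cov: int = 20
    noise_cov: int = 2
    noise_len: int = 8


class AssociationConfig(_Section):
    n_permutations: int = 1000
    identity: float = 0.80
    min_hit_len: int = 80
    flank: int = 1000


class ElementConfig(_Section):
    merge_dist: int = 1500
    canonical_len: int = 1500
    flank: int = 1000


class PipelineConfig(_Section):
    seed: int = 7
    genome: GenomeConfig = GenomeConfig()
    reads: ReadConfig = ReadConfig()
    sibling: SiblingConfig = SiblingConfig()
    kmer: KmerConfig = KmerConfig()
    mapping: MappingConfig = MappingConfig()
    genome_size: GenomeSizeConfig = GenomeSizeConfig()
    repeats: RepeatConfig = RepeatConfig()
    variants: VariantConfig = VariantConfig()
    deletions: DeletionConfig = DeletionConfig()
    association: AssociationConfig = AssociationConfig()
    elements: ElementConfig = ElementConfig()

    # single global seed fans out to per-stage seeds by fixed offsets
    def stage_seed(self, stage: str) -> int:
        offsets = {
            "genome": 0, "sibling": 1, "reads": 2, "sibling_reads": 3,
            "association": 4, "spans": 5, "rrna": 6,
        }
        return (self.seed + 1009 * offsets[stage]) % (2**31 - 1)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig(**payload)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
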