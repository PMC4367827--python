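"""Fixed differences between a reference species and a sibling read set,
partitioned by genomic region, with synonymous/non-synonymous and novel
stop codon classification, plus rRNA per-site variant profiling.

A site is called a fixed difference when it is covered by >= ``min_depth``
quality-filtered reads and the (near-)homozygous alternate allele reaches
the ``homozygous_freq`` threshold.  Rates are reported per *callable* site
(depth >= ``min_depth``), per region class (exon, intron, 5'/3' UTR,
non-coding; precedence exon > UTR > intron when annotations overlap).
Coding effects are evaluated jointly over all fixed differences in a
codon, which is what distinguishes a genuine novel stop codon from one
"compensated" by a second substitution in the same codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pileup import Pileup
from .simulate import REGION_CODES, REGION_NAMES

# standard genetic code; authoritative for effect classification here,
# cross-checked against an independent translation oracle in the tests
GENETIC_CODE = {}
_B = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _aa in enumerate(_AA):
    GENETIC_CODE[_B[_i // 16] + _B[(_i // 4) % 4] + _B[_i % 4]] = _aa

STOP_CODONS = {c for c, a in GENETIC_CODE.items() if a == "*"}


@dataclass
class VariantCall:
    scaffold: str
    pos: int
    ref: str
    alt: str
    freq: float
    depth: int
    vtype: str = "substitution"  # or "indel"
    indel_len: int = 0


def call_fixed_differences(
    pile: Pileup,
    reference: dict[str, str],
    min_depth: int = 10,
    homozygous_freq: float = 0.9,
) -> list[VariantCall]:
    """Homozygous substitution and short (1-2 bp) indel calls from a pileup."""
    calls: list[VariantCall] = []
    for ref_id, counts in pile.counts.items():
        seq = reference[ref_id]
        refcodes = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        rc = lut[refcodes]
        depth = counts.sum(axis=0)
        nonref = counts.copy()
        ok = rc < 4
        nonref[rc[ok], np.flatnonzero(ok)] = 0
        alt_idx = nonref.argmax(axis=0)
        alt_cnt = nonref.max(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(depth > 0, alt_cnt / np.maximum(depth, 1), 0.0)
        hit = (depth >= min_depth) & (freq >= homozygous_freq) & (alt_cnt > 0)
        for p in np.flatnonzero(hit):
            calls.append(
                VariantCall(ref_id, int(p), seq[p], "ACGT"[alt_idx[p]],
                            float(freq[p]), int(depth[p]))
            )
        for (rid, pos, dlen), cnt in pile.deletions.items():
            if rid != ref_id or dlen > 2:
                continue
            span = int(depth[pos]) + int(pile.del_span[rid][pos])
            if span >= min_depth and cnt / span >= homozygous_freq:
                calls.append(
                    VariantCall(rid, pos, seq[pos : pos + dlen], "-",
                                cnt / span, span, "indel", -dlen)
                )
        for (rid, pos, inserted), cnt in pile.insertions.items():
            if rid != ref_id or len(inserted) > 2 or pos >= depth.size:
                continue
            d = int(depth[pos])
            if d >= min_depth and cnt / d >= homozygous_freq:
                calls.append(
                    VariantCall(rid, pos, "-", inserted, cnt / d, d,
                                "indel", len(inserted))
                )
    calls.sort(key=lambda c: (c.scaffold, c.pos))
    return calls


# ---------------------------------------------------------------------------
# CDS model and coding effects


@dataclass
class CdsExon:
    start: int
    end: int
    phase: int


class CdsModel:
    """Coding structure of one gene on the forward strand: ordered CDS exons
    with phase; maps genomic positions to codon coordinates."""

    def __init__(self, gene: str, exons: list[CdsExon], sequence: str):
        self.gene = gene
        self.exons = sorted(exons, key=lambda e: e.start)
        cum = 0
        self._pos2cds: dict[int, int] = {}
        for ex in self.exons:
            expect = (3 - cum % 3) % 3
            if ex.phase != expect:
                raise ValueError(
                    f"phase inconsistency in {gene}: exon at {ex.start} has "
                    f"phase {ex.phase}, expected {expect}"
                )
            for g in range(ex.start, ex.end):
                self._pos2cds[g] = cum
                cum += 1
        self.cds_len = cum
        self.cds_seq = "".join(sequence[e.start : e.end] for e in self.exons)

    def codon_at(self, genomic_pos: int) -> tuple[int, int, str] | None:
        """(codon index, offset in codon, ref codon) or None outside CDS."""
        c = self._pos2cds.get(genomic_pos)
        if c is None:
            return None
        ci = c // 3
        codon = self.cds_seq[3 * ci : 3 * ci + 3]
        return (ci, c % 3, codon) if len(codon) == 3 else None


def classify_coding_effect(
    ref_codon: str, subs: list[tuple[int, str]]
) -> str:
    """Joint effect of all fixed differences in one codon.

    ``subs`` are (offset 0-2, alternate base).  Returns one of
    'synonymous', 'nonsynonymous', 'stop_gain', 'stop_compensated'.
    The joint codon (all substitutions applied) decides stop gain; a codon
    where some single substitution alone would create a stop that the joint
    codon does not is 'stop_compensated'.
    """
    if not subs:
        raise ValueError("no substitutions supplied")
    joint = list(ref_codon)
    for off, alt in subs:
        joint[off] = alt
    joint_c = "".join(joint)
    if joint_c in STOP_CODONS:
        return "stop_gain"
    singly_stopped = False
    for off, alt in subs:
        single = list(ref_codon)
        single[off] = alt
        if "".join(single) in STOP_CODONS:
            singly_stopped = True
    if singly_stopped:
        return "stop_compensated"
    return "synonymous" if GENETIC_CODE[joint_c] == GENETIC_CODE[ref_codon] else "nonsynonymous"


def _synonymous_site_fraction(codon: str) -> float:
    """Fraction of the 9 single-base changes of a codon that are synonymous
    (stop-producing changes count as non-synonymous opportunity)."""
    if codon in STOP_CODONS:
        return 0.0
    aa = GENETIC_CODE[codon]
    syn = 0
    for off in range(3):
        for b in "ACGT":
            if b == codon[off]:
                continue
            alt = codon[:off] + b + codon[off + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
                syn += 1
    return syn / 9.0


# ---------------------------------------------------------------------------
# region partition


@dataclass
class SubstitutionPartition:
    """Fixed-difference rates per region class plus coding-effect summary."""

    counts: dict[str, int] = field(default_factory=dict)
    callable_sites: dict[str, int] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)
    dn_count: int = 0
    ds_count: int = 0
    dn_rate: float = 0.0
    ds_rate: float = 0.0
    dnds_raw: float = float("nan")
    dnds_site_normalized: float = float("nan")
    novel_stops: int = 0
    compensated_stops: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "substitutions": self.counts.get(r, 0),
             "callable_sites": self.callable_sites.get(r, 0),
             "rate": self.rates.get(r, float("nan"))}
            for r in ("exon", "intron", "utr5", "utr3", "noncoding")
        ]
        return pd.DataFrame(rows)


def partition_by_region(
    calls: list[VariantCall],
    region: dict[str, np.ndarray],
    pile: Pileup,
    cds_models: dict[str, list[CdsModel]] | None = None,
    min_depth: int = 10,
) -> SubstitutionPartition:
    """Partition substitution calls by region class and classify coding
    effects jointly per codon.  ``region`` maps scaffold -> per-base region
    code array (see simulate.REGION_CODES); positions beyond the array are
    treated as non-coding.  Indels of 1-2 bp inside exons count as
    non-synonymous changes.
    """
    part = SubstitutionPartition()
    for name in REGION_CODES:
        part.counts[name] = 0
        part.callable_sites[name] = 0
    for ref_id, counts in pile.counts.items():
        depth = counts.sum(axis=0)
        callable_mask = depth >= min_depth
        codes = region.get(ref_id)
        if codes is None:
            part.callable_sites["noncoding"] += int(callable_mask.sum())
            continue
        for code, name in REGION_NAMES.items():
            part.callable_sites[name] += int(np.sum(callable_mask & (codes == code)))

    syn = nonsyn = stops = comp = 0
    # (scaffold, gene, codon index) -> (ref codon, substitutions in it)
    by_codon: dict[tuple[str, str, int], tuple[str, list[tuple[int, str]]]] = {}
    for call in calls:
        codes = region.get(call.scaffold)
        if codes is None or call.pos >= codes.size:
            cls = "noncoding"
        else:
            cls = REGION_NAMES[int(codes[call.pos])]
        if call.vtype == "indel":
            if cls == "exon" and abs(call.indel_len) <= 2:
                nonsyn += 1
            continue
        part.counts[cls] += 1
        if cls == "exon" and cds_models:
            for model in cds_models.get(call.scaffold, []):
                hit = model.codon_at(call.pos)
                if hit is not None:
                    ci, off, codon = hit
                    entry = by_codon.setdefault((call.scaffold, model.gene, ci), (codon, []))
                    entry[1].append((off, call.alt))
                    break
    for (codon, subs) in by_codon.values():
        effect = classify_coding_effect(codon, sorted(subs))
        if effect == "synonymous":
            syn += len(subs)
        elif effect == "nonsynonymous":
            nonsyn += len(subs)
        elif effect == "stop_gain":
            stops += 1
            nonsyn += len(subs)
        elif effect == "stop_compensated":
            comp += 1
            nonsyn += len(subs)

    part.dn_count, part.ds_count = nonsyn, syn
    part.novel_stops, part.compensated_stops = stops, comp
    exon_sites = part.callable_sites.get("exon", 0)
    for name in part.counts:
        sites = part.callable_sites.get(name, 0)
        part.rates[name] = part.counts[name] / sites if sites else float("nan")
    if exon_sites:
        part.dn_rate = nonsyn / exon_sites
        part.ds_rate = syn / exon_sites
        if syn:
            part.dnds_raw = nonsyn / syn
    # per-opportunity normalisation over all codons of the supplied models
    if cds_models:
        syn_frac = []
        for models in cds_models.values():
            for m in models:
                for ci in range(m.cds_len // 3):
                    codon = m.cds_seq[3 * ci : 3 * ci + 3]
                    if len(codon) == 3 and codon in GENETIC_CODE:
                        syn_frac.append(_synonymous_site_fraction(codon))
        if syn_frac and syn:
            fs = float(np.mean(syn_frac))
            if 0 < fs < 1:
                part.dnds_site_normalized = (nonsyn / (1 - fs)) / (syn / fs)
    return part


_GFF_TO_REGION = {
    "CDS": "exon",
    "exon": "exon",
    "intron": "intron",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def region_array_from_gff(records, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base region code arrays from GFF3 records.

    Overlaps resolve with precedence exon > UTR > intron (painted low to
    high); unannotated bases are non-coding.
    """
    arrays = {n: np.zeros(L, dtype=np.uint8) for n, L in lengths.items()}
    for cls in ("intron", "utr5", "utr3", "exon"):
        code = REGION_CODES[cls]
        for r in records:
            if _GFF_TO_REGION.get(r.type) == cls and r.seqid in arrays:
                arrays[r.seqid][r.start : r.end] = code
    return arrays


def cds_models_from_gff(records, sequences: dict[str, str]) -> dict[str, list[CdsModel]]:
    """Forward-strand CDS models per scaffold from GFF3 CDS rows (grouped by
    Parent attribute, phase taken from the phase column)."""
    grouped: dict[tuple[str, str], list[CdsExon]] = {}
    for r in records:
        if r.type != "CDS" or r.seqid not in sequences:
            continue
        gene = r.attrs.get("Parent", r.attrs.get("ID", f"{r.seqid}:{r.start}"))
        grouped.setdefault((r.seqid, gene), []).append(
            CdsExon(r.start, r.end, r.phase or 0)
        )
    out: dict[str, list[CdsModel]] = {}
    for (seqid, gene), exons in sorted(grouped.items()):
        out.setdefault(seqid, []).append(CdsModel(gene, exons, sequences[seqid]))
    return out


def cds_models_from_truth(truth, sequence: str) -> list[CdsModel]:
    """Build per-gene CDS models from planted gene structure."""
    by_gene: dict[str, list[CdsExon]] = {}
    for f in truth.by_type("exon"):
        by_gene.setdefault(f.name, []).append(
            CdsExon(f.start, f.end, int(f.attrs.get("phase", 0)))
        )
    return [CdsModel(g, exons, sequence) for g, exons in sorted(by_gene.items())]


# ---------------------------------------------------------------------------
# rRNA variant profiling


def rrna_variant_profile(
    pile: Pileup,
    consensus: str,
    unit_id: str = "rrna",
    window: int = 50,
    regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Per-position fraction of mapped bases differing from the consensus,
    with a sliding-window mean and optional region labels (18S/ITS/...).

    Zero-depth positions get NaN and are excluded from window means.
    """
    counts = pile.counts[unit_id][:, : len(consensus)]
    depth = counts.sum(axis=0)
    lut = {b: i for i, b in enumerate("ACGT")}
    ref_idx = np.array([lut.get(b, -1) for b in consensus])
    match = np.zeros(len(consensus))
    ok = ref_idx >= 0
    match[ok] = counts[ref_idx[ok], np.flatnonzero(ok)]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_frac = np.where(depth > 0, 1.0 - match / np.maximum(depth, 1), np.nan)
    df = pd.DataFrame(
        {"pos": np.arange(len(consensus)), "depth": depth, "variant_fraction": var_frac}
    )
    df["window_mean"] = (
        df["variant_fraction"].rolling(window, min_periods=1, center=True).mean()
    )
    df["region"] = ""
    if regions:
        for name, s, e in regions:
            df.loc[(df.pos >= s) & (df.pos < e), "region"] = name
    return df
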