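"""Synthetic genomes, sibling-species derivatives and short-read sets.

The generator emulates the composition of a tephritid-style genome at desk
scale: single-copy gene-like segments (with exon/intron/UTR structure and
CDS phase), alphoid-style satellite monomers (150-185 bp) arranged in long
head-to-tail tandem arrays, dispersed ~1.5 kb DNA-transposon copies (partly
fragmented), and uniform-coverage 100 bp reads with i.i.d. substitution
errors.  Every planted feature is recorded in a :class:`TruthSet` with exact
0-based half-open coordinates so downstream callers can be scored.

Sibling "species" are derived from a reference by applying per-region
substitution rates, non-overlapping deletions (>10 bp) and insert-size
jitter at transposon copies, again with full truth bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._seq import revcomp

REGION_CODES = {"noncoding": 0, "exon": 1, "intron": 2, "utr5": 3, "utr3": 4}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# codons never emitted inside a synthetic CDS
_STOPS = {"TAA", "TAG", "TGA"}


class PackingError(ValueError):
    """Planted features do not fit into the requested genome length."""


# ---------------------------------------------------------------------------
# specs


@dataclass
class SatelliteArraySpec:
    """A satellite family: ``monomer`` repeated head-to-tail ``copies`` times
    per array, ``arrays`` arrays planted."""

    monomer: str
    copies: int
    arrays: int = 1

    def __post_init__(self) -> None:
        if not 100 <= len(self.monomer) <= 300:
            raise ValueError("satellite monomer length must be in [100, 300]")


@dataclass
class TransposonSpec:
    """Dispersed element model: canonical ~1.5 kb sequence, number of planted
    copies and the fraction of copies planted as internal fragments."""

    sequence: str
    n_insertions: int
    fragmentation_rate: float = 0.5
    min_fragment: int = 200


@dataclass
class GeneSpec:
    """Gene-like segments: 5'UTR + CDS exon + intron + CDS exon + 3'UTR."""

    count: int
    length_range: tuple[int, int] = (900, 1500)
    utr_len: int = 60
    intron_len: int = 90


@dataclass
class GenomeSpec:
    length: int
    satellites: list[SatelliteArraySpec] = field(default_factory=list)
    transposon: TransposonSpec | None = None
    genes: GeneSpec | None = None
    seed: int = 0


@dataclass
class SiblingSpec:
    """Edits applied to a reference to derive a sibling species.

    ``substitution_rate_by_region`` maps region class names (exon, intron,
    utr5, utr3, noncoding) to per-base substitution probabilities in
    [0, 0.05].  ``deletions`` are explicit (start, length>10) reference
    intervals; alternatively ``n_random_deletions`` are auto-placed in
    feature-free sequence.  ``transposon_jitter_sd`` is the s.d. (bp) of the
    length change applied inside each planted transposon copy.
    """

    substitution_rate_by_region: dict[str, float] = field(default_factory=dict)
    deletions: list[tuple[int, int]] | None = None
    n_random_deletions: int = 0
    deletion_length_range: tuple[int, int] = (15, 80)
    transposon_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in self.substitution_rate_by_region.items():
            if name not in REGION_CODES:
                raise ValueError(f"unknown region class {name!r}")
            if not 0.0 <= rate <= 0.05:
                raise ValueError("substitution rates must lie in [0, 0.05]")


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class Feature:
    type: str
    start: int
    end: int
    name: str
    attrs: dict = field(default_factory=dict)


@dataclass
class TruthSet:
    """Exact record of everything planted (0-based half-open coordinates)."""

    genome_length: int
    features: list[Feature] = field(default_factory=list)
    region_edit_counts: dict[str, int] = field(default_factory=dict)
    substitution_positions: list[int] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    jitter: dict[str, int] = field(default_factory=dict)

    def by_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    def region_array(self) -> np.ndarray:
        """Per-base region class codes.  Precedence exon > UTR > intron."""
        arr = np.zeros(self.genome_length, dtype=np.uint8)
        for code_name in ("intron", "utr5", "utr3", "exon"):  # low to high
            code = REGION_CODES[code_name]
            for f in self.features:
                if f.type == code_name:
                    arr[f.start : f.end] = code
        return arr

    def feature_mask(self, types: tuple[str, ...] | None = None) -> np.ndarray:
        """Boolean mask of bases covered by any planted feature."""
        mask = np.zeros(self.genome_length, dtype=bool)
        for f in self.features:
            if types is None or f.type in types:
                mask[f.start : f.end] = True
        return mask

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["deletions"] = [list(d) for d in self.deletions]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        payload["features"] = [Feature(**f) for f in payload["features"]]
        payload["deletions"] = [tuple(d) for d in payload["deletions"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# sequence construction helpers


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def random_monomer(length: int, rng: np.random.Generator) -> str:
    return random_sequence(length, rng)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_sequence(3, rng)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _gene_block(spec: GeneSpec, idx: int, rng: np.random.Generator):
    """Build one gene-like segment; returns (sequence, sub-features)."""
    total = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    cds_len = total - 2 * spec.utr_len - spec.intron_len
    cds_len -= cds_len % 3
    if cds_len < 30:
        raise ValueError("gene length range too small for the fixed structure")
    cds = random_cds(cds_len // 3, rng)
    # split CDS across two exons at a codon-interior point to exercise phase
    cut = (cds_len // 2) - ((cds_len // 2) % 3) + 1  # phase of exon2 = 2
    utr5 = random_sequence(spec.utr_len, rng)
    utr3 = random_sequence(spec.utr_len, rng)
    intron = "GT" + random_sequence(spec.intron_len - 4, rng) + "AG"
    seq = utr5 + cds[:cut] + intron + cds[cut:] + utr3
    name = f"gene{idx:04d}"
    u = spec.utr_len
    i1_end = u + cut
    ex2_start = i1_end + spec.intron_len
    ex2_end = ex2_start + (cds_len - cut)
    feats = [
        ("gene", 0, len(seq), name, {}),
        ("utr5", 0, u, name, {}),
        ("exon", u, i1_end, name, {"phase": 0, "cds_index": 0}),
        ("intron", i1_end, ex2_start, name, {}),
        ("exon", ex2_start, ex2_end, name, {"phase": (3 - cut % 3) % 3, "cds_index": 1}),
        ("utr3", ex2_end, len(seq), name, {}),
    ]
    return seq, feats


def build_genome(spec: GenomeSpec) -> tuple[str, TruthSet]:
    """Assemble a synthetic genome and its exact truth set.

    Feature blocks (satellite arrays, transposon copies, gene segments) are
    placed in random order separated by random background sequence; the total
    length equals ``spec.length`` exactly.  Raises :class:`PackingError` when
    the features alone exceed the genome length.
    """
    rng = np.random.default_rng(spec.seed)
    blocks: list[tuple[str, list]] = []  # (sequence, sub-features)

    for si, sat in enumerate(spec.satellites):
        for ai in range(sat.arrays):
            arr_seq = sat.monomer * sat.copies
            blocks.append(
                (arr_seq, [("satellite", 0, len(arr_seq), f"sat{si}_arr{ai}",
                            {"monomer": sat.monomer, "copies": sat.copies})])
            )
    if spec.transposon is not None:
        tn = spec.transposon
        for ti in range(tn.n_insertions):
            if rng.random() < tn.fragmentation_rate and len(tn.sequence) > tn.min_fragment + 50:
                frag_len = int(rng.integers(tn.min_fragment, len(tn.sequence) - 49))
                off = int(rng.integers(0, len(tn.sequence) - frag_len + 1))
                seq = tn.sequence[off : off + frag_len]
                attrs = {"fragment": True, "offset": off}
            else:
                seq, attrs = tn.sequence, {"fragment": False, "offset": 0}
            blocks.append((seq, [("transposon", 0, len(seq), f"te{ti:04d}", attrs)]))
    if spec.genes is not None:
        for gi in range(spec.genes.count):
            blocks.append(_gene_block(spec.genes, gi, rng))

    total_feat = sum(len(b[0]) for b in blocks)
    if total_feat > spec.length:
        raise PackingError(
            f"features total {total_feat} bp exceed genome length {spec.length} bp"
        )
    order = rng.permutation(len(blocks))
    background = spec.length - total_feat
    # n_blocks+1 gaps summing to the background length
    cuts = np.sort(rng.integers(0, background + 1, size=len(blocks)))
    gaps = np.diff(np.concatenate(([0], cuts, [background])))

    truth = TruthSet(genome_length=spec.length)
    parts: list[str] = []
    pos = 0
    for gi, bi in enumerate(order):
        gap = int(gaps[gi])
        parts.append(random_sequence(gap, rng))
        pos += gap
        seq, feats = blocks[bi]
        parts.append(seq)
        for ftype, s, e, name, attrs in feats:
            truth.features.append(Feature(ftype, pos + s, pos + e, name, dict(attrs)))
        pos += len(seq)
    parts.append(random_sequence(int(gaps[-1]), rng))
    genome = "".join(parts)
    assert len(genome) == spec.length
    return genome, truth


# ---------------------------------------------------------------------------
# sibling derivation


def _place_random_deletions(
    truth: TruthSet, n: int, length_range: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping deletions in feature-free sequence, away from edges."""
    busy = truth.feature_mask()
    margin = 300
    out: list[tuple[int, int]] = []
    attempts = 0
    while len(out) < n and attempts < 100 * n:
        attempts += 1
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        pos = int(rng.integers(margin, truth.genome_length - margin - ln))
        if busy[pos - margin : pos + ln + margin].any():
            continue
        out.append((pos, ln))
        busy[pos - margin : pos + ln + margin] = True
    if len(out) < n:
        raise PackingError("could not place the requested random deletions")
    return sorted(out)


def derive_sibling(
    reference: str, truth: TruthSet, spec: SiblingSpec
) -> tuple[str, TruthSet]:
    """Apply per-region substitutions, deletions and transposon jitter.

    Returns the sibling sequence and a truth set recording realized per-region
    substitution counts, substitution positions, deletions (reference
    coordinates) and per-element length jitter.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(reference)
    if L != truth.genome_length:
        raise ValueError("reference length does not match truth set")
    region = truth.region_array()
    rate_by_code = np.zeros(5)
    for name, rate in spec.substitution_rate_by_region.items():
        rate_by_code[REGION_CODES[name]] = rate

    sub_mask = rng.random(L) < rate_by_code[region]
    sub_pos = np.flatnonzero(sub_mask)
    seq = np.frombuffer(reference.encode(), dtype=np.uint8).copy()
    # replace with a uniformly chosen *different* base
    for p in sub_pos:
        cur = seq[p]
        choices = _BASES[_BASES != cur]
        seq[p] = rng.choice(choices)

    out_truth = TruthSet(genome_length=L, features=list(truth.features))
    out_truth.substitution_positions = [int(p) for p in sub_pos]
    for code, name in REGION_NAMES.items():
        out_truth.region_edit_counts[name] = int(np.sum(region[sub_pos] == code))

    deletions = spec.deletions
    if deletions is None:
        deletions = (
            _place_random_deletions(truth, spec.n_random_deletions,
                                    spec.deletion_length_range, rng)
            if spec.n_random_deletions
            else []
        )
    deletions = sorted(deletions)
    for (s1, l1), (s2, _l2) in zip(deletions, deletions[1:]):
        if s1 + l1 > s2:
            raise ValueError(f"overlapping deletions at {s1} and {s2}")
    for s, ln in deletions:
        if ln <= 10:
            raise ValueError("planted deletions must exceed 10 bp")
        if not 0 <= s and s + ln <= L:
            raise ValueError("deletion outside reference")
    out_truth.deletions = list(deletions)

    # edits that change coordinates are applied right-to-left
    edits: list[tuple[int, int, str]] = [(s, ln, "") for s, ln in deletions]
    if spec.transposon_jitter_sd > 0:
        for f in truth.by_type("transposon"):
            delta = int(round(rng.normal(0.0, spec.transposon_jitter_sd)))
            out_truth.jitter[f.name] = delta
            mid = (f.start + f.end) // 2
            if delta > 0:
                edits.append((mid, 0, random_sequence(delta, rng)))
            elif delta < 0:
                ln = min(-delta, f.end - mid)
                edits.append((mid, ln, ""))
    chars = seq.tobytes().decode()
    for s, ln, ins in sorted(edits, reverse=True):
        chars = chars[:s] + ins + chars[s + ln :]
    return chars, out_truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSet:
    """Fixed-length short reads; mates are adjacent (r/1 then r/2) when paired."""

    ids: list[str]
    seqs: list[str]
    read_len: int
    paired: bool = False

    def __len__(self) -> int:
        return len(self.seqs)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))


def simulate_reads(
    sequence: str,
    depth: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    paired: bool = False,
    insert_mean: int = 300,
    insert_sd: int = 30,
    seed: int = 0,
) -> ReadSet:
    """Uniform-coverage reads from both strands with i.i.d. substitution errors.

    The expected number of reads is ``depth * len(sequence) / read_len``;
    start positions are uniform, each fragment is drawn from either strand
    with probability 0.5, and base qualities (when written to FASTQ) are the
    constant placeholder 'I'.
    """
    L = len(sequence)
    if L == 0:
        raise ValueError("cannot simulate reads from an empty sequence")
    if read_len > L:
        raise ValueError("read length exceeds sequence length")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * L / read_len))
    ids: list[str] = []
    seqs: list[str] = []
    if paired:
        n_pairs = max(1, n_reads // 2)
        inserts = np.clip(
            np.round(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
            read_len, max(read_len, min(L, insert_mean + 4 * insert_sd)),
        )
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
        flips = rng.random(n_pairs) < 0.5
        for i in range(n_pairs):
            s, ins = int(starts[i]), int(inserts[i])
            frag = sequence[s : s + ins]
            r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
            if flips[i]:
                r1, r2 = revcomp(frag[-read_len:]), frag[:read_len]
            ids += [f"r{i}/1", f"r{i}/2"]
            seqs += [r1, r2]
    else:
        starts = rng.integers(0, L - read_len + 1, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            s = int(starts[i])
            r = sequence[s : s + read_len]
            seqs.append(revcomp(r) if flips[i] else r)
            ids.append(f"r{i}")
    if error_rate > 0:
        total = len(seqs) * read_len
        n_err = rng.binomial(total, error_rate)
        flat = rng.integers(0, total, size=n_err)
        by_read: dict[int, list[int]] = {}
        for f in flat:
            by_read.setdefault(int(f) // read_len, []).append(int(f) % read_len)
        bases = "ACGT"
        for ri, positions in by_read.items():
            s = list(seqs[ri])
            for p in positions:
                others = bases.replace(s[p], "") or bases
                s[p] = others[int(rng.integers(0, len(others)))]
            seqs[ri] = "".join(s)
    return ReadSet(ids=ids, seqs=seqs, read_len=read_len, paired=paired)


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator, mask: np.ndarray | None = None
) -> tuple[str, list[int]]:
    """Substitute bases i.i.d. at ``rate`` (optionally only where ``mask``);
    returns the mutated sequence and substituted positions."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < rate
    if mask is not None:
        hit &= mask
    pos = np.flatnonzero(hit)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode(), [int(p) for p in pos]
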