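"""Repeat discovery from raw reads: greedy k-mer extension, iterative
align-and-extend consensus construction against an assembly, read-based
consensus finalization, redundancy culling and species-specific variant
libraries.

The extension walk operates on as-read (strand-directional) k-mer counts:
starting from the most abundant unconsumed k-mer, it repeatedly appends the
final base of the highest-count k-mer whose (k-1)-prefix equals the current
(k-1)-suffix, then extends leftwards symmetrically.  No k-mer is consumed
twice; a walk direction stops when the chosen k-mer has already been used
(which is how a tandem monomer closes on itself), when no candidate at or
above the count floor exists, or when the candidate count collapses
relative to the previous step (a repeat/unique boundary).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from ._seq import decode_kmer, encode, encode_kmer, min_rotation, mismatch_count, revcomp
from .kmers import KmerTable
from .mapping import ReferenceIndex, map_reads, _aligner
from .pileup import pileup_from_alignments


@dataclass
class RepeatConsensus:
    """A curated repeat sequence with class label and support statistics."""

    id: str
    sequence: str
    class_label: str = "unclassified"
    circular: bool = False
    support: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# greedy k-mer extension


def kmer_extend(
    table: KmerTable,
    top_n: int = 50000,
    min_extension: int = 50,
    min_count: int = 2,
    stop_ratio: float = 0.2,
    max_len: int = 10000,
) -> list[RepeatConsensus]:
    """Greedy single-base extension of the ``top_n`` most abundant k-mers.

    Seeds are processed in descending count order (lexicographic tie-break);
    seeds already consumed by a previous walk are skipped.  Only walks whose
    final length reaches ``k + min_extension`` are retained.  Walks that
    close on their own seed k-mer are flagged circular (tandem monomers) and
    reported in lexicographically minimal rotation of their repeat period.

    A direction stops when the chosen candidate's count falls below
    ``stop_ratio`` of the walk's running peak count: at a repeat/unique
    boundary the continuation splits across the copies' distinct flanks, so
    the drop relative to the previous step alone can be gradual even though
    the drop relative to the repeat's interior is sharp.
    """
    if table.strand_policy != "as-read":
        raise ValueError("kmer_extend requires an as-read k-mer table")
    k = table.k
    mask = (1 << (2 * (k - 1))) - 1
    hi_shift = 2 * (k - 1)
    lookup = table.lookup
    consumed: set[int] = set()
    out: list[RepeatConsensus] = []
    bases = "ACGT"

    def best_right(suffix: int):
        best = None
        for b in range(4):
            cand = (suffix << 2) | b
            c = lookup.get(cand, 0)
            if c >= min_count and (best is None or c > best[1]):
                best = (cand, c, b)
        return best

    def best_left(prefix: int):
        best = None
        for b in range(4):
            cand = (b << hi_shift) | prefix
            c = lookup.get(cand, 0)
            if c >= min_count and (best is None or c > best[1]):
                best = (cand, c, b)
        return best

    for seed_code, seed_count in table.most_common(top_n):
        if seed_code in consumed or seed_count < min_count:
            continue
        consumed.add(seed_code)
        right: list[str] = []
        circular = False
        suffix = seed_code & mask
        peak = seed_count
        while len(right) + k < max_len:
            cand = best_right(suffix)
            if cand is None or cand[1] < stop_ratio * peak:
                break
            if cand[0] in consumed:
                circular = cand[0] == seed_code
                break
            consumed.add(cand[0])
            right.append(bases[cand[2]])
            suffix = cand[0] & mask
            peak = max(peak, cand[1])
        left: list[str] = []
        prefix = seed_code >> 2
        peak = seed_count
        while len(left) + len(right) + k < max_len:
            cand = best_left(prefix)
            if cand is None or cand[1] < stop_ratio * peak:
                break
            if cand[0] in consumed:
                break
            consumed.add(cand[0])
            left.append(bases[cand[2]])
            prefix = cand[0] >> 2
            peak = max(peak, cand[1])
        seq = "".join(reversed(left)) + decode_kmer(seed_code, k) + "".join(right)
        if len(seq) < k + min_extension:
            continue
        if circular:
            period = len(seq) - (k - 1)
            seq = min_rotation(seq[:period])
        out.append(
            RepeatConsensus(
                id=f"rep{len(out):04d}",
                sequence=seq,
                circular=circular,
                support={"seed_count": seed_count},
            )
        )
    return out


# ---------------------------------------------------------------------------
# pairwise identity / culling


def pairwise_identity(a: str, b: str, max_exact_len: int = 3000) -> float:
    """Identity of the shorter sequence against the longer (free end gaps on
    the longer), best of both orientations.  Long pairs (> ``max_exact_len``)
    are screened by shared 12-mer containment instead of full alignment."""
    if len(a) > len(b):
        a, b = b, a
    if not a:
        return 0.0
    if len(a) > max_exact_len:
        ka = {a[i : i + 12] for i in range(len(a) - 11)}
        kb = {b[i : i + 12] for i in range(len(b) - 11)}
        krc = {revcomp(x) for x in kb}
        return max(len(ka & kb), len(ka & krc)) / max(1, len(ka))
    aligner = _aligner()
    best = 0.0
    for query in (a, revcomp(a)):
        aln = aligner.align(b, query)[0]
        tb, qb = aln.aligned
        matches = 0
        for (ts, te), (qs, qe) in zip(tb, qb):
            matches += sum(1 for x, y in zip(b[ts:te], query[qs:qe]) if x == y)
        best = max(best, matches / len(a))
    return best


def _shares_kmers(a: str, b: str, k: int = 12, frac: float = 0.2) -> bool:
    sa = {a[i : i + k] for i in range(0, max(1, len(a) - k + 1))}
    sb = {b[i : i + k] for i in range(0, max(1, len(b) - k + 1))}
    sb |= {revcomp(x) for x in sb}
    small = min(len(sa), len(sb))
    return len(sa & sb) >= frac * small


def cull_redundant(
    lib: list[RepeatConsensus], max_identity: float = 0.80
) -> list[RepeatConsensus]:
    """Drop entries with > ``max_identity`` to a longer retained entry.

    Circular (tandem-monomer) entries are compared against the doubled
    retained sequence so that rotated and reverse-complement versions of
    the same monomer are recognised as redundant.
    """
    ordered = sorted(lib, key=lambda r: (-len(r.sequence), r.id))
    kept: list[RepeatConsensus] = []
    for cand in ordered:
        redundant = False
        for ref in kept:
            if not _shares_kmers(cand.sequence, ref.sequence):
                continue
            target = ref.sequence
            if (cand.circular or ref.circular) and len(target) <= 600:
                target = target + target  # rotation-tolerant comparison
            if pairwise_identity(cand.sequence, target) > max_identity:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda r: r.id)
    return kept


# ---------------------------------------------------------------------------
# align-and-extend against an assembly


def _find_matches(
    consensus: str,
    index: ReferenceIndex,
    min_identity: float,
    max_clusters: int = 400,
):
    """Genomic matches of ``consensus`` at >= ``min_identity``; returns a
    list of (global_start, global_end) intervals in index coordinates."""
    k = index.seed_len
    L = len(consensus)
    diag_hits: Counter = Counter()
    for orient_seq, orient in ((consensus, "+"), (revcomp(consensus), "-")):
        for o in range(0, L - k + 1, k):
            code_seq = orient_seq[o : o + k]
            if "N" in code_seq:
                continue
            for hit in index.seed_hits(encode_kmer(code_seq)):
                diag_hits[(orient, int(hit) - o)] += 1
    # cluster nearby diagonals per orientation
    matches: list[tuple[int, int, str]] = []
    seen_spans: list[tuple[int, int]] = []
    aligner = _aligner()
    for orient in ("+", "-"):
        diags = sorted(d for (o, d) in diag_hits if o == orient)
        clusters: list[list[int]] = []
        for d in diags:
            if clusters and d - clusters[-1][-1] <= 40:
                clusters[-1].append(d)
            else:
                clusters.append([d])
        clusters.sort(key=lambda c: -max(diag_hits[(orient, d)] for d in c))
        oriented = consensus if orient == "+" else revcomp(consensus)
        rcodes = encode(oriented)
        for cluster in clusters[:max_clusters]:
            diag = max(cluster, key=lambda d: diag_hits[(orient, d)])
            if diag < 0 or diag + L > len(index.concat):
                continue
            mm = mismatch_count(index.codes, diag, rcodes)
            if mm <= (1 - min_identity) * L:
                span = (diag, diag + L)
            else:
                w0, w1 = max(0, diag - 100), min(len(index.concat), diag + L + 100)
                aln = aligner.align(index.concat[w0:w1], oriented)[0]
                tb, qb = aln.aligned
                if len(tb) == 0:
                    continue
                matches_n = 0
                cols = 0
                for (ts, te), (qs, qe) in zip(tb, qb):
                    seg = index.concat[w0 + ts : w0 + te]
                    matches_n += sum(1 for x, y in zip(seg, oriented[qs:qe]) if x == y)
                    cols += te - ts
                qcov = (qb[-1][1] - qb[0][0]) / L
                if cols == 0 or matches_n / max(cols, 1) < min_identity or qcov < 0.8:
                    continue
                span = (w0 + int(tb[0][0]), w0 + int(tb[-1][1]))
            if any(not (span[1] <= s or span[0] >= e) for s, e in seen_spans):
                continue
            seen_spans.append(span)
            matches.append((span[0], span[1], orient))
    return matches


def find_fragments(
    sequence: str,
    index: ReferenceIndex,
    min_identity: float = 0.80,
    min_len: int = 80,
    max_clusters: int = 2000,
) -> list[tuple[int, int]]:
    """Genomic fragments of ``sequence`` (global index coordinates).

    Blast-like: every 12-mer-seeded diagonal is end-trimmed to its best
    matching stretch; stretches >= ``min_len`` at >= ``min_identity`` are
    kept and overlapping hits merged.
    """
    from .mapping import _trim_ungapped

    k = index.seed_len
    L = len(sequence)
    spans: list[tuple[int, int]] = []
    for oriented in (sequence, revcomp(sequence)):
        diag_hits: Counter = Counter()
        for o in range(0, L - k + 1, k):
            kmer = oriented[o : o + k]
            if "N" in kmer:
                continue
            for hit in index.seed_hits(encode_kmer(kmer)):
                diag_hits[int(hit) - o] += 1
        diags = sorted(diag_hits)
        clusters: list[list[int]] = []
        for d in diags:
            if clusters and d - clusters[-1][-1] <= 30:
                clusters[-1].append(d)
            else:
                clusters.append([d])
        rcodes = encode(oriented)
        for cluster in clusters[:max_clusters]:
            diag = max(cluster, key=lambda d: diag_hits[d])
            if diag < 0 or diag + L > len(index.concat):
                continue
            hit = _trim_ungapped(index.codes, diag, rcodes)
            if hit is None:
                continue
            ops, gpos, nm, _score = hit
            span_len = dict(ops).get("M", 0)
            if span_len >= min_len and 1 - nm / span_len >= min_identity:
                spans.append((gpos, gpos + span_len))
    spans.sort()
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def align_and_extend(
    seed: RepeatConsensus,
    assembly: dict[str, str] | str,
    flank: int = 200,
    consensus_threshold: float = 0.60,
    min_identity: float = 0.80,
    min_support: int = 3,
    max_iter: int = 25,
) -> RepeatConsensus:
    """Iteratively extend a repeat consensus using its genomic copies.

    Each round finds assembly matches at >= ``min_identity``, extracts the
    matched segments with up to ``flank`` bp of flanking sequence, stacks the
    flanks column-by-column and extends the consensus while at least
    ``min_support`` segments cover the column and >= ``consensus_threshold``
    of them agree.  Iteration stops when no direction grows.
    """
    if isinstance(assembly, str):
        assembly = {"ref": assembly}
    if len(seed.sequence) < 50:
        raise ValueError("align_and_extend requires a seed of >= 50 bp")
    index = ReferenceIndex(assembly, seed_len=12)
    concat = index.concat
    consensus = seed.sequence
    n_matches = 0
    for _ in range(max_iter):
        matches = _find_matches(consensus, index, min_identity)
        n_matches = len(matches)
        if n_matches == 0:
            warnings.warn(f"{seed.id}: no assembly matches; seed returned unchanged")
            return RepeatConsensus(seed.id, seed.sequence, seed.class_label,
                                   support={"n_matches": 0})
        if n_matches < min_support:
            break
        lefts, rights = [], []
        for s, e, orient in matches:
            lf = concat[max(0, s - flank) : s]
            rf = concat[e : e + flank]
            if orient == "-":
                lf, rf = revcomp(rf), revcomp(lf)
            lefts.append(lf)
            rights.append(rf)

        def grow(flanks: list[str], reverse: bool) -> str:
            cols = []
            j = 0
            while True:
                chars = []
                for f in flanks:
                    if j < len(f):
                        chars.append(f[len(f) - 1 - j] if reverse else f[j])
                chars = [c for c in chars if c in "ACGT"]
                if len(chars) < min_support:
                    break
                base, cnt = Counter(chars).most_common(1)[0]
                if cnt / len(chars) < consensus_threshold:
                    break
                cols.append(base)
                j += 1
            return "".join(cols)

        right_ext = grow(rights, reverse=False)
        left_ext = grow(lefts, reverse=True)[::-1]
        if not right_ext and not left_ext:
            break
        consensus = left_ext + consensus + right_ext
    return RepeatConsensus(
        seed.id, consensus, seed.class_label, support={"n_matches": n_matches}
    )


# ---------------------------------------------------------------------------
# finalization against reads


def _tiled_library(lib: list[RepeatConsensus], read_len: int):
    """Mapping reference per entry; short (satellite-like) entries are tandem
    tiled so junction reads align without clipping.  Returns the reference
    dict and the tie-collapse period per entry."""
    ref: dict[str, str] = {}
    periods: dict[str, int] = {}
    for entry in lib:
        seq = entry.sequence
        if len(seq) < 2 * read_len:
            tiles = -(-2 * read_len // len(seq))  # ceil
            ref[entry.id] = seq * tiles + seq[: read_len]
            periods[entry.id] = len(seq)
        else:
            ref[entry.id] = seq
            periods[entry.id] = 0
    return ref, periods


def _fold_counts(counts, period: int, length: int):
    """Sum tiled pileup columns back onto the repeat unit."""
    import numpy as np

    if period == 0:
        return counts[:, :length]
    folded = np.zeros((4, period), dtype=counts.dtype)
    for start in range(0, counts.shape[1], period):
        chunk = counts[:, start : start + period]
        folded[:, : chunk.shape[1]] += chunk
    return folded[:, :length]


def map_to_library(lib: list[RepeatConsensus], reads, min_q: int = 20):
    """Map reads to the (tiled) library; returns (alignments, pileup-per-entry,
    mapped read count, mean NM over retained alignments)."""
    read_len = reads.read_len if hasattr(reads, "read_len") else 100
    ref, periods = _tiled_library(lib, read_len)
    index = ReferenceIndex(ref, seed_len=19)
    alignments = map_reads(reads, index, tie_period=periods)
    retained = [a for a in alignments if a.mapq > min_q]
    pile = pileup_from_alignments(alignments, {n: len(s) for n, s in ref.items()}, min_q)
    folded = {
        e.id: _fold_counts(pile.counts[e.id], periods[e.id], len(e.sequence))
        for e in lib
    }
    mean_nm = sum(a.nm for a in retained) / len(retained) if retained else 0.0
    return retained, folded, pile, periods


def finalize_consensus(
    lib: list[RepeatConsensus], reads, min_q: int = 20, max_identity: float = 0.80
) -> tuple[list[RepeatConsensus], dict]:
    """Install per-position majority bases from the reads, cull redundant
    entries (> ``max_identity`` to a longer entry, longer kept) and report
    the mapped-read fraction and mean NM over retained alignments.

    Redundant entries are culled *before* mapping as well: with an exact
    reverse-complement duplicate in the library every error-free read ties
    between the two copies (q=0), and only error-carrying reads would vote
    on the consensus."""
    import numpy as np

    if not lib:
        raise ValueError("empty repeat library")
    lib = cull_redundant(lib, max_identity)
    retained, folded, _pile, _periods = map_to_library(lib, reads, min_q)
    polished: list[RepeatConsensus] = []
    for entry in lib:
        counts = folded[entry.id]
        seq = list(entry.sequence)
        depth = counts.sum(axis=0)
        maj = counts.argmax(axis=0)
        for i in range(len(seq)):
            if depth[i] > 0:
                seq[i] = "ACGT"[maj[i]]
        polished.append(
            RepeatConsensus(entry.id, "".join(seq), entry.class_label,
                            entry.circular, dict(entry.support))
        )
    polished = cull_redundant(polished, max_identity)
    n_reads = len(reads) if hasattr(reads, "__len__") else None
    mapped_ids = {a.read_id for a in retained}
    stats = {
        "mapped_read_fraction": (len(mapped_ids) / n_reads) if n_reads else float("nan"),
        "mean_nm": (sum(a.nm for a in retained) / len(retained)) if retained else 0.0,
        "n_entries": len(polished),
    }
    for entry in polished:
        entry.support["mapped_read_fraction"] = stats["mapped_read_fraction"]
        entry.support["mean_nm"] = stats["mean_nm"]
    return polished, stats


def species_specific_variants(
    lib: list[RepeatConsensus],
    sibling_reads,
    min_q: int = 20,
    min_freq: float = 0.5,
    species_tag: str = "sibling",
) -> list[RepeatConsensus]:
    """Substitute sites where the sibling-majority allele differs at a
    frequency strictly above ``min_freq``; apply small (1-2 bp) indels the
    same way.  Entries with zero coverage are returned unchanged, flagged."""
    import numpy as np

    retained, folded, pile, periods = map_to_library(lib, sibling_reads, min_q)
    out: list[RepeatConsensus] = []
    for entry in lib:
        counts = folded[entry.id]
        depth = counts.sum(axis=0)
        if depth.sum() == 0:
            rc = RepeatConsensus(entry.id, entry.sequence, entry.class_label,
                                 entry.circular, dict(entry.support))
            rc.support["zero_coverage"] = True
            out.append(rc)
            continue
        seq = list(entry.sequence)
        maj = counts.argmax(axis=0)
        for i, cur in enumerate(seq):
            if depth[i] == 0:
                continue
            top = "ACGT"[maj[i]]
            if top != cur and counts[maj[i], i] / depth[i] > min_freq:
                seq[i] = top
        # small indels from pileup evidence, folded onto the unit
        L = len(entry.sequence)
        period = periods[entry.id]
        edits: list[tuple[int, int, str]] = []
        ins_fold: Counter = Counter()
        for (rid, pos, inserted), cnt in pile.insertions.items():
            if rid == entry.id and len(inserted) <= 2:
                ins_fold[(pos % period if period else pos, inserted)] += cnt
        for (upos, inserted), cnt in ins_fold.items():
            if upos < L and depth[upos] > 0 and cnt / depth[upos] > min_freq:
                edits.append((upos, 0, inserted))
        del_fold: Counter = Counter()
        for (rid, pos, dlen), cnt in pile.deletions.items():
            if rid == entry.id and dlen <= 2:
                del_fold[(pos % period if period else pos, dlen)] += cnt
        for (upos, dlen), cnt in del_fold.items():
            denom = depth[upos] + cnt if upos < L else 0
            if upos < L and denom > 0 and cnt / denom > min_freq:
                edits.append((upos, dlen, ""))
        new_seq = "".join(seq)
        for s, dlen, ins in sorted(edits, reverse=True):
            new_seq = new_seq[:s] + ins + new_seq[s + dlen :]
        rc = RepeatConsensus(f"{entry.id}|{species_tag}", new_seq,
                             entry.class_label, entry.circular, dict(entry.support))
        out.append(rc)
    return out
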