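"""Pairwise contig alignment reduced to the identity x coverage score.

The species-level dereplication, chimera detection and dairy-database
matching all rest on one scalar per contig pair: alignment identity
(matches over aligned columns) times coverage (aligned fraction of the
*shorter* contig). This module computes it either from an internal
seed-and-extend aligner (exact k-mer seeds chained per diagonal, ungapped
x-drop extension on both strands) or from externally produced PSL rows.

The ungapped extension is adequate for the substitution-only synthetic
communities this package simulates; gapped alignments produced by an
external aligner enter through the PSL path and are scored identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import ContigRecord

logger = logging.getLogger("rindvirome")

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a target contig.

    Blocks are half-open 0-based (q_start, q_end, t_start, t_end) intervals,
    non-overlapping on the query. Identity is matches / aligned_length.
    """

    query_id: str
    target_id: str
    blocks: tuple[tuple[int, int, int, int], ...]
    matches: int
    aligned_length: int
    identity: float
    coverage: float
    query_length: int
    target_length: int
    strand: str = "+"

    @property
    def score(self) -> float:
        return self.identity * self.coverage


@dataclass(frozen=True)
class AlignParams:
    """Seed-and-extend parameters (a lightweight BLAT-like configuration)."""

    k: int = 11                 # exact seed word size
    min_seed_hits: int = 2      # seeds required in a diagonal chain before extension
    match: int = 1
    mismatch: int = -1
    xdrop: int = 20             # stop extending when score drops this far below its max
    min_hit_length: int = 100   # discard hits shorter than this many aligned bp
    max_kmer_occurrence: int = 8  # mask seeds from words more frequent than this
    max_seed_gap: int = 200     # seeds further apart than this start a new chain

    def __post_init__(self) -> None:
        if self.k < 5:
            raise ValueError("seed word size k must be >= 5")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class _SeqProfile:
    """Cached numeric views of one sequence: base codes plus sorted k-mer index."""

    def __init__(self, seq: str, k: int, max_occ: int):
        self.arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        self.length = len(seq)
        self.codes, self.positions = _kmer_codes(self.arr, k)
        if self.codes.size:
            order = np.argsort(self.codes, kind="stable")
            codes_sorted = self.codes[order]
            # mask overrepresented words (repeat masking, as seed aligners do)
            uniq, starts, counts = np.unique(codes_sorted, return_index=True, return_counts=True)
            keep_mask = np.ones(codes_sorted.size, dtype=bool)
            for s, c in zip(starts[counts > max_occ], counts[counts > max_occ]):
                keep_mask[s:s + c] = False
            self.sorted_codes = codes_sorted[keep_mask]
            self.sorted_positions = self.positions[order][keep_mask]
        else:
            self.sorted_codes = self.codes
            self.sorted_positions = self.positions


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes of every k-mer free of N, with their positions."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = arr[i:i + n]
        codes = codes * 4 + np.where(window == 4, 0, window)
        valid &= window != 4
    positions = np.nonzero(valid)[0]
    return codes[valid], positions


def _seed_diagonals(qp: _SeqProfile, tp: _SeqProfile) -> tuple[np.ndarray, np.ndarray]:
    """All seed matches between the two profiles as (diagonal, query-position) pairs."""
    if qp.sorted_codes.size == 0 or tp.sorted_codes.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lo = np.searchsorted(tp.sorted_codes, qp.sorted_codes, side="left")
    hi = np.searchsorted(tp.sorted_codes, qp.sorted_codes, side="right")
    counts = hi - lo
    has = counts > 0
    if not has.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    c, l = counts[has], lo[has]
    q_pos = np.repeat(qp.sorted_positions[has], c)
    # enumerate target positions for each matching run without a Python loop
    ends = np.cumsum(c)
    idx = np.arange(ends[-1]) - np.repeat(ends - c, c) + np.repeat(l, c)
    t_pos = tp.sorted_positions[idx]
    return q_pos - t_pos, q_pos


def _extend_on_diagonal(
    q_arr: np.ndarray,
    t_arr: np.ndarray,
    diag: int,
    seed_lo: int,
    seed_hi: int,
    k: int,
    params: AlignParams,
) -> tuple[int, int, int] | None:
    """Ungapped x-drop extension of the seed span on one diagonal.

    Returns (q_start, q_end, matches) or None when the hit is too short.
    """
    q0 = max(0, diag)
    q1 = min(q_arr.size, t_arr.size + diag)
    if q1 - q0 < params.min_hit_length:
        return None
    m = (q_arr[q0:q1] == t_arr[q0 - diag:q1 - diag]) & (q_arr[q0:q1] != 4)
    vals = np.where(m, params.match, params.mismatch)
    core_lo = max(seed_lo, q0) - q0
    core_hi = min(seed_hi + k, q1) - q0

    def arm(values: np.ndarray) -> int:
        """Length of the best x-drop extension along ``values``."""
        if values.size == 0:
            return 0
        cs = np.cumsum(values)
        running = np.maximum.accumulate(cs)
        dead = np.nonzero(cs < running - params.xdrop)[0]
        limit = dead[0] if dead.size else values.size
        if limit == 0:
            return 0
        best = int(np.argmax(cs[:limit]))
        return best + 1 if cs[best] > 0 else 0

    left = arm(vals[:core_lo][::-1])
    right = arm(vals[core_hi:])
    start = core_lo - left
    end = core_hi + right
    if end - start < params.min_hit_length:
        return None
    matches = int(m[start:end].sum())
    return q0 + start, q0 + end, matches


def _align_profiles(
    a_id: str,
    b_id: str,
    ap: _SeqProfile,
    bp: _SeqProfile,
    strand: str,
    params: AlignParams,
) -> list[AlignmentHit]:
    diags, q_pos = _seed_diagonals(ap, bp)
    hits: list[AlignmentHit] = []
    if diags.size == 0:
        return hits
    order = np.lexsort((q_pos, diags))
    diags, q_pos = diags[order], q_pos[order]
    uniq, starts, counts = np.unique(diags, return_index=True, return_counts=True)
    for d, s, c in zip(uniq, starts, counts):
        if c < params.min_seed_hits:
            continue
        # chain seeds on this diagonal: a gap beyond max_seed_gap starts a new chain
        pos = q_pos[s:s + c]
        breaks = np.nonzero(np.diff(pos) > params.max_seed_gap)[0] + 1
        spans: list[tuple[int, int]] = []
        for chain in np.split(pos, breaks):
            # need min_seed_hits seeds including two that do not overlap
            # (a single shared 12-mer yields two overlapping 11-mer seeds)
            if chain.size < params.min_seed_hits or chain[-1] - chain[0] < params.k:
                continue
            span = _extend_on_diagonal(
                ap.arr, bp.arr, int(d), int(chain[0]), int(chain[-1]), params.k, params
            )
            if span is not None:
                spans.append(span[:2])
        if not spans:
            continue
        # merge chains whose extensions overlap, then recount matches per block
        merged = _merge_intervals(spans)
        q0_full = max(0, int(d))
        q1_full = min(ap.length, bp.length + int(d))
        qs = ap.arr[q0_full:q1_full]
        m = (qs == bp.arr[q0_full - int(d):q1_full - int(d)]) & (qs != 4)
        for q_start, q_end in merged:
            alen = q_end - q_start
            if alen < params.min_hit_length:
                continue
            matches = int(m[q_start - q0_full:q_end - q0_full].sum())
            t_start, t_end = q_start - int(d), q_end - int(d)
            if strand == "-":
                # report target coordinates on the forward strand
                t_start, t_end = bp.length - t_end, bp.length - t_start
            hits.append(
                AlignmentHit(
                    query_id=a_id,
                    target_id=b_id,
                    blocks=((q_start, q_end, t_start, t_end),),
                    matches=matches,
                    aligned_length=alen,
                    identity=matches / alen,
                    coverage=min(1.0, alen / min(ap.length, bp.length)),
                    query_length=ap.length,
                    target_length=bp.length,
                    strand=strand,
                )
            )
    return hits


def align_pair(a: ContigRecord, b: ContigRecord, params: AlignParams = AlignParams()) -> list[AlignmentHit]:
    """Local ungapped alignments of ``a`` (query) against both strands of ``b``."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    ap = _SeqProfile(a.sequence, params.k, params.max_kmer_occurrence)
    bp_fwd = _SeqProfile(b.sequence, params.k, params.max_kmer_occurrence)
    hits = _align_profiles(a.id, b.id, ap, bp_fwd, "+", params)
    bp_rev = _SeqProfile(revcomp(b.sequence), params.k, params.max_kmer_occurrence)
    hits += _align_profiles(a.id, b.id, ap, bp_rev, "-", params)
    return hits


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def pair_score(hits: Sequence[AlignmentHit], a_len: int, b_len: int) -> float:
    """Identity x coverage for one ordered contig pair.

    Coverage is the union of query blocks over the length of the shorter
    contig; identity is the match-weighted mean over all hits. An empty hit
    set scores 0.
    """
    if not hits:
        return 0.0
    # greedy non-redundant selection: best hits first, keep a hit only if most
    # of it covers query ground not already covered (drops shadow hits that
    # would otherwise drag the match-weighted identity down)
    selected: list[AlignmentHit] = []
    union: list[tuple[int, int]] = []
    for h in sorted(hits, key=lambda h: (-h.matches, h.blocks)):
        h_blocks = [(q0, q1) for (q0, q1, _, _) in h.blocks]
        h_len = sum(q1 - q0 for q0, q1 in h_blocks)
        new_union = _merge_intervals(union + h_blocks)
        gain = sum(e - s for s, e in new_union) - sum(e - s for s, e in union)
        if gain >= 0.5 * h_len:
            selected.append(h)
            union = new_union
    union_len = sum(e - s for s, e in union)
    coverage = min(1.0, union_len / min(a_len, b_len))
    total_matches = sum(h.matches for h in selected)
    total_alen = sum(h.aligned_length for h in selected)
    identity = min(1.0, total_matches / total_alen)
    return identity * coverage


def self_alignment_fraction(
    c: ContigRecord,
    params: AlignParams = AlignParams(),
    include_trivial: bool = True,
) -> float:
    """Total self-aligned bases over contig length (>= 1 for any contig).

    A repeat-free contig aligns only to itself end-to-end (fraction 1.0);
    internal duplications add further hits and push the fraction above 1,
    which is the chimera signature used by the catalog (threshold 110%).
    Query-side block lengths are summed across distinct hits; the trivial
    full-length self-hit is included by default.
    """
    hits = align_pair(c, c, params)
    total = 0
    for h in hits:
        is_trivial = h.strand == "+" and h.blocks[0][0] == h.blocks[0][2]
        if is_trivial and not include_trivial:
            continue
        total += sum(q1 - q0 for (q0, q1, _, _) in h.blocks)
    if include_trivial and not any(
        h.strand == "+" and h.blocks[0][0] == h.blocks[0][2] for h in hits
    ):
        total += c.length  # degenerate short sequence: count the identity hit anyway
    return total / c.length


def all_vs_all(
    contigs: Sequence[ContigRecord],
    params: AlignParams = AlignParams(),
    psl_hits: Iterable[AlignmentHit] | None = None,
) -> dict[tuple[str, str], float]:
    """Sparse symmetric table of pair scores over all unordered contig pairs.

    When ``psl_hits`` is given (e.g. from :func:`rindvirome.io.read_psl`)
    the internal aligner is bypassed and the same union/score reduction is
    applied to the external hits.
    """
    ids = [c.id for c in contigs]
    if len(ids) != len(set(ids)):
        raise ValueError("contig ids must be unique")
    lengths = {c.id: c.length for c in contigs}
    scores: dict[tuple[str, str], float] = {}
    if psl_hits is not None:
        by_pair: dict[tuple[str, str], list[AlignmentHit]] = {}
        for h in psl_hits:
            if h.query_id == h.target_id:
                continue
            key = tuple(sorted((h.query_id, h.target_id)))
            by_pair.setdefault(key, []).append(h)
        for (x, y), hits in by_pair.items():
            a_len = lengths.get(x, hits[0].query_length)
            b_len = lengths.get(y, hits[0].target_length)
            s = pair_score(hits, a_len, b_len)
            if s > 0:
                scores[(x, y)] = s
        return scores

    profiles = {
        c.id: (
            _SeqProfile(c.sequence, params.k, params.max_kmer_occurrence),
            _SeqProfile(revcomp(c.sequence), params.k, params.max_kmer_occurrence),
        )
        for c in contigs
    }
    for a, b in combinations(contigs, 2):
        ap = profiles[a.id][0]
        hits = _align_profiles(a.id, b.id, ap, profiles[b.id][0], "+", params)
        hits += _align_profiles(a.id, b.id, ap, profiles[b.id][1], "-", params)
        s = pair_score(hits, a.length, b.length)
        if s > 0:
            key = tuple(sorted((a.id, b.id)))
            scores[key] = s
    logger.info("all-vs-all alignment: %d contigs, %d scored pairs", len(contigs), len(scores))
    return scores


def score_lookup(scores: Mapping[tuple[str, str], float], a: str, b: str) -> float:
    if a == b:
        return 1.0
    return scores.get(tuple(sorted((a, b))), 0.0)
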