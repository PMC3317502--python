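"""Ungapped short-read mapping and per-base coverage expression calling.

Reads of fixed length L are placed ungapped, full length, on either strand
of a set of reference transcript sequences.  A placement scores
``matches - cost * mismatches`` (N never matches) and is accepted when the
score reaches ``ceil(0.8 * L)``; each read takes its single best accepted
placement, ties broken by reference order, then leftmost position, then
'+' strand.  Per-base depth over accepted placements gives each reference
a percent-mapped value; a transcript is called expressed when coverage is
strictly greater than the expression threshold (default 99%).

The two-pass protocol maps first at mismatch cost 2 and then re-maps at
the more permissive cost 1; the expressed call is made on the final pass.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

ACCEPT_FRACTION = 0.8
DEFAULT_EXPRESSION_THRESHOLD = 99.0


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    reference_id: str
    position: int  # 0-based offset on the reference forward strand
    strand: str
    mismatches: int
    score: int


@dataclass(frozen=True)
class CoverageReport:
    reference_id: str
    exonic_length: int
    covered_bases: int
    percent_mapped: float
    expressed: bool

    @property
    def percent_mapped_int(self) -> int:
        """Integer percentage for tabular reports."""
        return int(round(self.percent_mapped))


_BASE_INDEX = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


class ReferenceIndex:
    """Sliding-window view over a reference set for fixed-length reads.

    Read bases are compared bytewise; 'N' in a read is remapped so it can
    never equal a reference base, and 'N' in a reference never matches a
    read base.  For batch mapping the index also caches one-hot window
    matrices so match counting becomes four matrix products.
    """

    def __init__(self, references: dict[str, str]):
        if not references:
            raise ValueError("empty reference set")
        self.ids = list(references)
        self.seqs = {k: v.upper() for k, v in references.items()}
        self._window_cache: dict[int, list[tuple[str, np.ndarray]]] = {}
        self._onehot_cache: dict[int, list[tuple[str, np.ndarray]]] = {}

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.seqs.items()}

    def _windows(self, L: int) -> list[tuple[str, np.ndarray]]:
        if L not in self._window_cache:
            out = []
            for rid in self.ids:
                seq = self.seqs[rid]
                if len(seq) < L:
                    out.append((rid, np.empty((0, L), dtype=np.uint8)))
                    continue
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                arr[arr == ord("N")] = 255  # reference N matches nothing
                out.append(
                    (rid, np.lib.stride_tricks.sliding_window_view(arr, L))
                )
            self._window_cache[L] = out
        return self._window_cache[L]

    def _onehot_windows(self, L: int) -> list[tuple[str, np.ndarray]]:
        """Per reference: (4*L, W) float32 one-hot of sliding windows.

        Row i*4+c is 1 where window position i holds base c, so a read
        one-hot (R, 4*L) times this matrix counts matches in one GEMM.
        """
        if L not in self._onehot_cache:
            out = []
            for rid, windows in self._windows(L):
                if windows.shape[0] == 0:
                    continue
                idx = _BASE_INDEX[windows]  # (W, L); N/255 -> 4 (no channel)
                W = windows.shape[0]
                oh = np.zeros((W, L, 4), dtype=np.float32)
                ii, jj = np.nonzero(idx < 4)
                oh[ii, jj, idx[ii, jj]] = 1.0
                out.append((rid, np.ascontiguousarray(oh.reshape(W, 4 * L).T)))
            self._onehot_cache[L] = out
        return self._onehot_cache[L]


def _encode_read(read: str) -> np.ndarray:
    arr = np.frombuffer(read.upper().encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0  # read N matches nothing
    return arr


def _onehot_reads(encoded: np.ndarray) -> np.ndarray:
    """(R, L) uint8 byte codes -> (R, 4*L) float32 one-hot."""
    idx = _BASE_INDEX[encoded]
    R, L = encoded.shape
    oh = np.zeros((R, L, 4), dtype=np.float32)
    ii, jj = np.nonzero(idx < 4)
    oh[ii, jj, idx[ii, jj]] = 1.0
    return oh.reshape(R, 4 * L)


def map_read(
    read_id: str,
    read: str,
    index: ReferenceIndex,
    mismatch_cost: int = 2,
) -> ReadPlacement | None:
    """Best accepted ungapped full-length placement, or None if unmapped.

    An equal-scoring read is assigned by a deterministic read-keyed draw
    (CRC32 of the read id modulo the full tied candidate set, enumerated
    in reference order, '+' strand first, left to right).  These
    receptors are internally repetitive (tandem Ig-domain copies) and
    paralogs share long identical stretches, so any fixed positional
    preference would starve all but the first copy of its multi-mapping
    reads and bias coverage downward.  Because score orders placements
    exactly as mismatch count does at either cost, the tied set is the
    same at cost 2 and cost 1, so re-mapping at the permissive cost can
    only add placements, never move them.
    """
    if mismatch_cost not in (1, 2):
        raise ValueError("mismatch_cost must be 1 or 2")
    L = len(read)
    min_score = math.ceil(ACCEPT_FRACTION * L)
    fwd = _encode_read(read)
    rev = _encode_read(str(Seq(read).reverse_complement()))
    # pass 1: best score per (reference, strand) without materialising ties
    scored: list[tuple[str, str, np.ndarray]] = []
    top = min_score - 1
    for rid, windows in index._windows(L):
        if windows.shape[0] == 0:
            continue
        for strand, enc in (("+", fwd), ("-", rev)):
            mm = np.count_nonzero(windows != enc, axis=1)
            scores = L - (1 + mismatch_cost) * mm
            best = int(scores.max())
            if best >= min_score:
                scored.append((rid, strand, scores))
                top = max(top, best)
    if not scored:
        return None
    tied: list[tuple[str, str, int, int]] = []
    for rid, strand, scores in scored:
        for j in np.nonzero(scores == top)[0]:
            tied.append((rid, strand, int(j), (L - int(scores[j])) // (1 + mismatch_cost)))
    rid, strand, pos, mm_count = (
        tied[0] if len(tied) == 1 else tied[zlib.crc32(read_id.encode()) % len(tied)]
    )
    return ReadPlacement(
        read_id=read_id,
        reference_id=rid,
        position=pos,
        strand=strand,
        mismatches=mm_count,
        score=top,
    )


def _batch_candidates(
    read_items: list[tuple[str, str]],
    index: ReferenceIndex,
    chunk_size: int = 512,
) -> list[tuple[str, str, int, int] | None]:
    """Best placement candidate per read, before any acceptance cutoff.

    All reads must share one length.  Returns, per read, the chosen
    (reference_id, strand, position, mismatches) — the same read-keyed
    draw over the tied minimal-mismatch set as ``map_read`` — or None
    when no reference is long enough.  Match counting is done as four
    one-hot matrix products per (reference, strand), which is what makes
    whole-library mapping tractable.
    """
    L = len(read_items[0][1])
    assert all(len(s) == L for _, s in read_items)
    refts = index._onehot_windows(L)
    if not refts:
        return [None] * len(read_items)
    results: list[tuple[str, str, int, int] | None] = []
    for lo in range(0, len(read_items), chunk_size):
        chunk = read_items[lo : lo + chunk_size]
        R = len(chunk)
        enc = {
            "+": np.stack([_encode_read(s) for _, s in chunk]),
            "-": np.stack(
                [_encode_read(str(Seq(s).reverse_complement())) for _, s in chunk]
            ),
        }
        oh = {st: _onehot_reads(enc[st]) for st in "+-"}
        mats: list[tuple[str, str, np.ndarray, np.ndarray]] = []
        top = np.zeros(R, dtype=np.float32)
        for rid, refT in refts:
            for st in "+-":
                M = oh[st] @ refT  # (R, W) float32 match counts
                mx = M.max(axis=1)
                mats.append((rid, st, M, mx))
                np.maximum(top, mx, out=top)
        cands: list[list[tuple[str, str, int]]] = [[] for _ in range(R)]
        for rid, st, M, mx in mats:
            for r in np.nonzero(mx >= top - 0.5)[0]:
                for p in np.nonzero(M[r] >= top[r] - 0.5)[0]:
                    cands[r].append((rid, st, int(p)))
        for r, (read_id, _) in enumerate(chunk):
            tied = cands[r]
            mm = L - int(round(float(top[r])))
            if len(tied) == 1:
                rid, st, pos = tied[0]
            else:
                rid, st, pos = tied[zlib.crc32(read_id.encode()) % len(tied)]
            results.append((rid, st, pos, mm))
    return results


def map_reads(
    reads: dict[str, str],
    index: ReferenceIndex,
    mismatch_cost: int = 2,
) -> list[ReadPlacement]:
    """Map a read library; equivalent to ``map_read`` per read but batched."""
    if mismatch_cost not in (1, 2):
        raise ValueError("mismatch_cost must be 1 or 2")
    by_length: dict[int, list[tuple[str, str]]] = {}
    for rid, seq in reads.items():
        by_length.setdefault(len(seq), []).append((rid, seq))
    placements = []
    for L, items in by_length.items():
        min_score = math.ceil(ACCEPT_FRACTION * L)
        for (read_id, _), cand in zip(items, _batch_candidates(items, index)):
            if cand is None:
                continue
            rid, strand, pos, mm = cand
            score = L - (1 + mismatch_cost) * mm
            if score >= min_score:
                placements.append(
                    ReadPlacement(read_id, rid, pos, strand, mm, score)
                )
    placements.sort(key=lambda p: p.read_id)
    return placements


def positional_coverage(
    placements: list[ReadPlacement],
    reference_id: str,
    reference_length: int,
    read_length: int,
) -> np.ndarray:
    """Per-base depth for fixed-length reads on one reference."""
    depth = np.zeros(reference_length, dtype=np.int64)
    for p in placements:
        if p.reference_id != reference_id:
            continue
        if p.position + read_length > reference_length:
            raise ValueError("placement overhangs reference end")
        depth[p.position : p.position + read_length] += 1
    return depth


def coverage_report(
    reference_id: str,
    depth: np.ndarray,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> CoverageReport:
    """Summarise a depth array into a percent-mapped / expressed call.

    The expressed call is strict: exactly at the threshold is NOT expressed
    (the rule is "more than" the threshold percentage).
    """
    n = int(depth.shape[0])
    if n < 1:
        raise ValueError("reference length must be >= 1")
    covered = int(np.count_nonzero(depth))
    percent = 100.0 * covered / n
    return CoverageReport(
        reference_id=reference_id,
        exonic_length=n,
        covered_bases=covered,
        percent_mapped=percent,
        expressed=percent > expression_threshold,
    )


def region_coverage(
    placements: list[ReadPlacement],
    references: dict[str, str],
    regions: list[tuple[str, str, int, int]],
    read_length: int,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> dict[str, CoverageReport]:
    """Coverage of sub-intervals of larger references (genomic protocol).

    ``regions`` is a list of (region_id, reference_id, start, end) with
    0-based half-open coordinates on the reference.  Depth is computed
    per reference once; each region's percent mapped counts only its own
    bases.  This mirrors mapping transcript reads onto chromosomal
    segments and asking what fraction of each predicted gene region the
    mapped reads cover.
    """
    depth_by_ref = {
        rid: positional_coverage(placements, rid, len(seq), read_length)
        for rid, seq in references.items()
    }
    out = {}
    for region_id, rid, start, end in regions:
        if not 0 <= start < end <= len(references[rid]):
            raise ValueError(f"region {region_id} outside reference {rid}")
        rep = coverage_report(region_id, depth_by_ref[rid][start:end],
                              expression_threshold)
        out[region_id] = rep
    return out


def _two_pass_placements(
    reads: dict[str, str],
    index: ReferenceIndex,
    cost_first: int,
    cost_second: int,
) -> tuple[list[ReadPlacement], list[ReadPlacement]]:
    """Placements at both costs from one shared mapping.

    A placement's mismatch count is cost-independent (score is a strictly
    decreasing function of mismatches at either cost), so the minimal-
    mismatch candidate — and the tied set the read-keyed draw chooses
    from — is identical at both costs; only the acceptance cutoff moves.
    """
    by_length: dict[int, list[tuple[str, str]]] = {}
    for rid, seq in reads.items():
        by_length.setdefault(len(seq), []).append((rid, seq))
    out: tuple[list[ReadPlacement], list[ReadPlacement]] = ([], [])
    for L, items in by_length.items():
        min_score = math.ceil(ACCEPT_FRACTION * L)
        cands = _batch_candidates(items, index)
        for (read_id, _), cand in zip(items, cands):
            if cand is None:
                continue
            rid, strand, pos, mm = cand
            for k, cost in enumerate((cost_first, cost_second)):
                score = L - (1 + cost) * mm
                if score >= min_score:
                    out[k].append(
                        ReadPlacement(read_id, rid, pos, strand, mm, score)
                    )
    for placements in out:
        placements.sort(key=lambda p: p.read_id)
    return out


def two_pass_region_coverage(
    reads: dict[str, str],
    references: dict[str, str],
    regions: list[tuple[str, str, int, int]],
    read_length: int,
    cost_first: int = 2,
    cost_second: int = 1,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> tuple[dict[str, CoverageReport], dict[str, CoverageReport], list[ReadPlacement]]:
    """Two-pass mapping against large references with per-region calls."""
    index = ReferenceIndex(references)
    first_pl, final_pl = _two_pass_placements(reads, index, cost_first, cost_second)
    first = region_coverage(
        first_pl, references, regions, read_length, expression_threshold
    )
    final = region_coverage(
        final_pl, references, regions, read_length, expression_threshold
    )
    return first, final, final_pl


def two_pass_coverage(
    reads: dict[str, str],
    references: dict[str, str],
    read_length: int,
    cost_first: int = 2,
    cost_second: int = 1,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> tuple[dict[str, CoverageReport], dict[str, CoverageReport], list[ReadPlacement]]:
    """Map at the strict cost, re-map at the permissive cost, call expression.

    Returns (first-pass reports, final reports, final placements); the
    expressed call comes from the final (permissive) pass.
    """
    if not reads:
        warnings.warn("no reads supplied; all transcripts report 0% coverage")
    index = ReferenceIndex(references)
    lengths = index.lengths()
    first_pl, final_pl = (
        _two_pass_placements(reads, index, cost_first, cost_second)
        if reads
        else ([], [])
    )

    def reports(placements: list[ReadPlacement]) -> dict[str, CoverageReport]:
        out = {}
        for rid in index.ids:
            depth = positional_coverage(placements, rid, lengths[rid], read_length)
            out[rid] = coverage_report(rid, depth, expression_threshold)
        return out

    return reports(first_pl), reports(final_pl), final_pl
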