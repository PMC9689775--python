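"""Consolidate multi-tool TE annotation calls and filter mapped copies.

Two filters mirror the curation applied between de novo annotation and the
genome-wide copy map:

* :func:`dedup_calls` merges the call sets of several annotation tools by
  removing over-long artifacts (> 10 kb by default) and resolving conflicts
  where two calls on the same chromosome and strand overlap by more than 20%
  of the shorter call, keeping one call per conflict.
* :func:`filter_mapped` drops low-quality mapped copies (score <= 1 by
  default) and, within any chain of location-overlapping copies, keeps only
  the copy with the highest mapping score.

Both are deterministic and idempotent; input order never changes the result.
"""

from __future__ import annotations

from intervaltree import IntervalTree

from socialte.models import IntervalError, MappedTE, TECall


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def calls_conflict(a: TECall, b: TECall, max_overlap_frac: float) -> bool:
    """Two calls conflict if same chrom+strand and they overlap by more than
    ``max_overlap_frac`` of the shorter call."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    ov = _overlap_bp(a.start, a.end, b.start, b.end)
    if ov == 0:
        return False
    return ov / min(a.length, b.length) > max_overlap_frac


def _call_priority(c: TECall):
    # longer first; ties: earlier start, then lexicographic tool id
    return (-c.length, c.start, c.tool, c.chrom, c.strand, c.call_id)


def dedup_calls(
    calls: list[TECall],
    max_overlap_frac: float = 0.20,
    max_len: int = 10_000,
) -> list[TECall]:
    """Deduplicate combined multi-tool TE calls.

    Calls longer than ``max_len`` are removed first, then a greedy sweep in
    priority order (longer call wins; ties by earlier start, then tool id)
    retains a call only if it conflicts with no already-retained call. Exact
    duplicates (overlap fraction 1) collapse to a single call. Opposite-strand
    overlaps are not conflicts: strand is part of the element's identity.

    Returns the retained subset in (chrom, start, end, strand, tool) order.
    """
    if not 0 <= max_overlap_frac <= 1:
        raise ValueError(f"max_overlap_frac must be in [0,1], got {max_overlap_frac}")
    for c in calls:
        if c.start >= c.end:  # dataclass validates, but inputs may bypass it
            raise IntervalError(f"malformed call {c}")
    survivors = [c for c in calls if c.length <= max_len]
    kept: list[TECall] = []
    trees: dict[tuple[str, str], IntervalTree] = {}
    for c in sorted(survivors, key=_call_priority):
        tree = trees.setdefault((c.chrom, c.strand), IntervalTree())
        conflict = any(
            calls_conflict(c, iv.data, max_overlap_frac) for iv in tree.overlap(c.start, c.end)
        )
        if not conflict:
            kept.append(c)
            tree.addi(c.start, c.end, c)
    return sorted(kept, key=lambda c: (c.chrom, c.start, c.end, c.strand, c.tool))


def dedup_calls_bruteforce(
    calls: list[TECall],
    max_overlap_frac: float = 0.20,
    max_len: int = 10_000,
) -> list[TECall]:
    """Exhaustive pairwise-check oracle for :func:`dedup_calls`.

    Applies the identical priority order but compares each candidate against
    every retained call with no index structure. Intended for testing on
    small inputs only (quadratic).
    """
    survivors = [c for c in calls if c.length <= max_len]
    kept: list[TECall] = []
    for c in sorted(survivors, key=_call_priority):
        if all(not calls_conflict(c, k, max_overlap_frac) for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: (c.chrom, c.start, c.end, c.strand, c.tool))


def filter_mapped(
    copies: list[MappedTE],
    min_score_exclusive: float = 1.0,
) -> list[MappedTE]:
    """Filter genome-mapped TE copies.

    Copies with score <= ``min_score_exclusive`` are removed as low quality.
    Remaining copies that overlap by >= 1 bp on the same chromosome (any
    strand: mapped copies compete for genomic space) are chained into
    connected components; only the highest-scoring member of each chain is
    retained, ties broken by earlier start then copy id.
    """
    survivors = [m for m in copies if m.score > min_score_exclusive]
    out: list[MappedTE] = []
    by_chrom: dict[str, list[MappedTE]] = {}
    for m in survivors:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom_copies in by_chrom.values():
        chrom_copies.sort(key=lambda m: (m.start, m.end, m.copy_id))
        chain: list[MappedTE] = []
        chain_end = -1
        for m in chrom_copies:
            if chain and m.start >= chain_end:
                out.append(min(chain, key=lambda x: (-x.score, x.start, x.copy_id)))
                chain = []
                chain_end = -1
            chain.append(m)
            chain_end = max(chain_end, m.end)
        if chain:
            out.append(min(chain, key=lambda x: (-x.score, x.start, x.copy_id)))
    return sorted(out, key=lambda m: (m.chrom, m.start, m.end, m.copy_id))
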