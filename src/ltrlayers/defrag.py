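"""Overlap resolution and adjacent-fragment merging.

Aligners routinely report one repeat copy as several overlapping or abutting
hits.  ``resolve_overlaps`` makes hits pairwise disjoint on the genome
(higher score wins; the loser is trimmed or dropped) and ``merge_adjacent``
fuses consecutive hits of the same family/part/strand that continue each
other on the consensus into longer candidate pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .formats import Fragment

DEFAULT_GAP_TOL = 100
DEFAULT_CONS_TOL = 30


@dataclass
class Candidate:
    """A contiguous piece of one element copy, built from >= 1 fragments.

    ``covered`` lists the consensus intervals (1-based inclusive, sorted,
    non-overlapping) supported by the member fragments.
    """

    contig_id: str
    g_start: int
    g_end: int
    strand: str
    family_id: str
    part: str
    covered: list[tuple[int, int]]
    members: list[Fragment]
    score: float
    consensus_length: int | None = None

    @property
    def g_len(self) -> int:
        return self.g_end - self.g_start + 1

    @property
    def covered_length(self) -> int:
        return sum(e - s + 1 for s, e in self.covered)

    @property
    def completeness(self) -> float | None:
        if not self.consensus_length:
            return None
        return self.covered_length / self.consensus_length

    @property
    def c_first(self) -> int:
        """First covered consensus position."""
        return self.covered[0][0]

    @property
    def c_last(self) -> int:
        """Last covered consensus position."""
        return self.covered[-1][1]


def _sort_key(f: Fragment):
    return (f.contig_id, f.g_start, f.g_end, f.family_id, f.part, f.c_start)


def _subtract(start: int, end: int, kept: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Remaining sub-intervals of [start, end] after removing ``kept``."""
    pieces = [(start, end)]
    for ks, ke in kept:
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            if ke < s or ks > e:
                nxt.append((s, e))
                continue
            if s < ks:
                nxt.append((s, ks - 1))
            if e > ke:
                nxt.append((ke + 1, e))
        pieces = nxt
    return pieces


def _trim_fragment(f: Fragment, new_start: int, new_end: int) -> Fragment:
    """Trim a fragment to a genomic sub-interval, shrinking its consensus
    interval proportionally (orientation-aware)."""
    if (new_start, new_end) == (f.g_start, f.g_end):
        return f
    ratio = f.c_len / f.g_len
    left_cut = new_start - f.g_start
    right_cut = f.g_end - new_end
    if f.strand == "+":
        c_start = f.c_start + round(left_cut * ratio)
        c_end = f.c_end - round(right_cut * ratio)
    else:
        c_start = f.c_start + round(right_cut * ratio)
        c_end = f.c_end - round(left_cut * ratio)
    if c_end < c_start:  # degenerate rounding; keep a 1-bp stub
        c_end = c_start
    scale = (new_end - new_start + 1) / f.g_len
    return replace(
        f,
        g_start=new_start,
        g_end=new_end,
        c_start=c_start,
        c_end=c_end,
        score=f.score * scale,
    )


def resolve_overlaps(
    fragments: Iterable[Fragment],
    min_len: int = 100,
    min_identity: float = 80.0,
) -> list[Fragment]:
    """Make fragments pairwise non-overlapping per contig.

    Fragments are taken in decreasing score order; each is trimmed to the
    longest genomic remainder not already claimed by a higher-scoring
    fragment and dropped if that remainder (or the original) is shorter than
    ``min_len`` or its identity is below ``min_identity``.  Output is
    genome-sorted.
    """
    frags = [
        f
        for f in fragments
        if f.g_len >= min_len and f.identity >= min_identity
    ]
    # score desc; ties resolved by genomic position for determinism
    frags.sort(key=lambda f: (-f.score, f.contig_id, f.g_start, f.g_end, f.family_id, f.part))
    kept_per_contig: dict[str, list[tuple[int, int]]] = {}
    out: list[Fragment] = []
    for f in frags:
        kept = kept_per_contig.setdefault(f.contig_id, [])
        pieces = _subtract(f.g_start, f.g_end, kept)
        if not pieces:
            continue
        # longest remainder, leftmost on ties
        s, e = max(pieces, key=lambda p: (p[1] - p[0], -p[0]))
        if e - s + 1 < min_len:
            continue
        out.append(_trim_fragment(f, s, e))
        kept.append((s, e))
    out.sort(key=_sort_key)
    return out


def _as_candidate(f: Fragment, lengths: Mapping[tuple[str, str], int] | None) -> Candidate:
    clen = lengths.get((f.family_id, f.part)) if lengths else None
    return Candidate(
        contig_id=f.contig_id,
        g_start=f.g_start,
        g_end=f.g_end,
        strand=f.strand,
        family_id=f.family_id,
        part=f.part,
        covered=[(f.c_start, f.c_end)],
        members=[f],
        score=f.score,
        consensus_length=clen,
    )


def _can_merge(prev: Candidate, nxt: Candidate, gap_tol: int, cons_tol: int) -> bool:
    if (
        prev.contig_id != nxt.contig_id
        or prev.family_id != nxt.family_id
        or prev.part != nxt.part
        or prev.strand != nxt.strand
    ):
        return False
    gap = nxt.g_start - prev.g_end - 1
    if gap < 0 or gap > gap_tol:
        return False
    if prev.strand == "+":
        # next must continue the consensus where prev left off
        return abs(nxt.c_first - (prev.c_last + 1)) <= cons_tol
    # minus strand: genome order walks the consensus backwards
    return abs(prev.c_first - (nxt.c_last + 1)) <= cons_tol


def _merge_covered(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _fuse(prev: Candidate, nxt: Candidate) -> Candidate:
    return Candidate(
        contig_id=prev.contig_id,
        g_start=prev.g_start,
        g_end=nxt.g_end,
        strand=prev.strand,
        family_id=prev.family_id,
        part=prev.part,
        covered=_merge_covered(prev.covered + nxt.covered),
        members=prev.members + nxt.members,
        score=prev.score + nxt.score,
        consensus_length=prev.consensus_length or nxt.consensus_length,
    )


def merge_candidates(
    candidates: list[Candidate],
    gap_tol: int = DEFAULT_GAP_TOL,
    cons_tol: int = DEFAULT_CONS_TOL,
) -> list[Candidate]:
    """Fuse consecutive genome-sorted candidates that continue each other."""
    ordered = sorted(candidates, key=lambda c: (c.contig_id, c.g_start, c.g_end))
    out: list[Candidate] = []
    for cand in ordered:
        if out and _can_merge(out[-1], cand, gap_tol, cons_tol):
            out[-1] = _fuse(out[-1], cand)
        else:
            out.append(cand)
    return out


def merge_adjacent(
    fragments: Iterable[Fragment],
    gap_tol: int = DEFAULT_GAP_TOL,
    cons_tol: int = DEFAULT_CONS_TOL,
    library=None,
) -> list[Candidate]:
    """Merge overlap-resolved fragments into candidate LTR/IN pieces.

    Consecutive fragments of identical (family, part, strand) whose genomic
    gap is within ``gap_tol`` and whose consensus coordinates continue
    (within ``cons_tol``, orientation-aware) become one Candidate; everything
    else becomes a singleton.  ``library`` (a list of entries or a
    ``(family, part) -> length`` mapping) enables completeness computation.
    """
    lengths: Mapping[tuple[str, str], int] | None
    if library is None:
        lengths = None
    elif isinstance(library, Mapping):
        lengths = library
    else:
        from .formats import library_lengths

        lengths = library_lengths(library)
    singles = [_as_candidate(f, lengths) for f in sorted(fragments, key=_sort_key)]
    return merge_candidates(singles, gap_tol, cons_tol)
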