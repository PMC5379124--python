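"""Link-state assignment and recursive layer resolution.

Candidate pieces on one contig are compared pairwise with a four-branch
decision procedure (LTR-LTR, IN-IN, LTR-IN, IN-LTR) yielding one of three
states: 0 (not linked), 1 (linked), 2 (inserted).  State 1 fires either on a
*continuation* (two pieces of the same copy whose consensus coordinates
continue each other) or a *part transition* (an LTR reaching its consensus
end followed by an IN starting at consensus position 1, or the mirror).
State 2 marks a candidate lying between two pieces that continue each other
across it: the hallmark of a nested insertion.

Chains are grown by a left-to-right greedy scan; candidates marked inserted
form the pool for the next layer, recursively, so layer i elements are
interrupted only by layer i+1 elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Iterable, Mapping, Sequence

from .defrag import Candidate


class LinkState(IntEnum):
    NOT_LINKED = 0
    LINKED = 1
    INSERTED = 2


@dataclass(frozen=True)
class LinkParams:
    """Tolerances for the pairwise link decision.

    g_direct bounds the (insert-corrected) genomic gap of a direct link;
    g_insert bounds how far ahead a continuation may be sought over
    inserted material.
    """

    cons_tol: int = 30
    end_tol: int = 20
    g_direct: int = 200
    g_insert: int = 20_000

    def __post_init__(self) -> None:
        if min(self.cons_tol, self.end_tol, self.g_direct, self.g_insert) < 0:
            raise ValueError("link tolerances must be non-negative")
        if self.g_direct > self.g_insert:
            raise ValueError("g_direct must not exceed g_insert")


@dataclass
class Chain:
    """One linked block domain: an ordered (genome order) run of candidates
    reconstructing a single element."""

    members: list[Candidate]
    contig_id: str
    strand: str
    layer: int = 0
    host: "Chain | None" = None

    @property
    def g_start(self) -> int:
        return min(c.g_start for c in self.members)

    @property
    def g_end(self) -> int:
        return max(c.g_end for c in self.members)

    @property
    def g_span(self) -> int:
        return self.g_end - self.g_start + 1


LengthMap = Mapping[tuple[str, str], int]


def _lengths(library) -> LengthMap:
    if library is None:
        return {}
    if isinstance(library, Mapping):
        return library
    from .formats import library_lengths

    return library_lengths(library)


def continuation_ok(x: Candidate, y: Candidate, cons_tol: int) -> bool:
    """Same-part continuation test: does y (genome-after x) carry on x's
    consensus coverage?  On the minus strand genome order walks the
    consensus backwards, so the roles swap."""
    if x.part != y.part:
        return False
    if x.strand == "+":
        return abs(y.c_first - (x.c_last + 1)) <= cons_tol
    return abs(x.c_first - (y.c_last + 1)) <= cons_tol


def transition_ok(
    x: Candidate, y: Candidate, lengths: LengthMap, end_tol: int
) -> bool:
    """Part-transition test (element-oriented).

    Plus strand: an LTR whose coverage reaches its consensus end followed by
    an IN starting near consensus position 1 (branch LTR-IN), or the mirror
    IN-LTR giving a 3' LTR.  Minus strand evaluates the mirror pair order.
    """
    if x.part == y.part:
        return False
    if x.strand == "-":
        x, y = y, x  # genome order is reversed element order on '-'
    xlen = lengths.get((x.family_id, x.part))
    if xlen is None:
        return False
    return x.c_last >= xlen - end_tol and y.c_first <= 1 + end_tol


def _pair_state1(
    x: Candidate,
    y: Candidate,
    lengths: LengthMap,
    params: LinkParams,
    effective_gap: int,
    raw_gap: int,
) -> bool:
    if (
        x.family_id != y.family_id
        or x.strand != y.strand
        or x.contig_id != y.contig_id
    ):
        return False
    if raw_gap < 0:
        return False
    if x.part == y.part:
        # continuation may bridge inserted material: use the gap net of
        # intervening candidates
        return (
            effective_gap <= params.g_direct
            and continuation_ok(x, y, params.cons_tol)
        )
    # part transitions must be (nearly) direct: an insertion exactly at an
    # LTR/IN junction is not bridged (ambiguous breakpoint ownership)
    return raw_gap <= params.g_direct and transition_ok(x, y, lengths, params.end_tol)


def _index_of(ordered: Sequence[Candidate], c: Candidate) -> int:
    for i, o in enumerate(ordered):
        if o is c:
            return i
    raise ValueError("candidate not found in ordered list")


def _effective_gap(ordered: Sequence[Candidate], ix: int, iz: int) -> int:
    """Genomic gap between candidates ix and iz minus the genome covered by
    candidates strictly between them."""
    x, z = ordered[ix], ordered[iz]
    raw = z.g_start - x.g_end - 1
    covered = 0
    for k in range(ix + 1, iz):
        c = ordered[k]
        lo = max(c.g_start, x.g_end + 1)
        hi = min(c.g_end, z.g_start - 1)
        if hi >= lo:
            covered += hi - lo + 1
    return raw - covered


def link_state(
    x: Candidate,
    y: Candidate,
    ordered: Sequence[Candidate],
    library,
    params: LinkParams = LinkParams(),
) -> LinkState:
    """Assign the link state of the ordered pair (x, y).

    1: x and y satisfy a branch rule (continuation or part transition).
    2: some z after y, within ``g_insert`` of x, continues x while y lies
       strictly between them and fails its own test with x.
    0: otherwise.
    """
    if x.contig_id != y.contig_id:
        raise ValueError(
            f"candidates on different contigs: {x.contig_id} vs {y.contig_id}"
        )
    lengths = _lengths(library)
    ix = _index_of(ordered, x)
    iy = _index_of(ordered, y)
    if iy <= ix:
        raise ValueError("y must follow x in the ordered candidate list")
    if _pair_state1(
        x, y, lengths, params, _effective_gap(ordered, ix, iy),
        y.g_start - x.g_end - 1,
    ):
        return LinkState.LINKED
    for iz in range(iy + 1, len(ordered)):
        z = ordered[iz]
        if z.contig_id != x.contig_id:
            break
        if z.g_start - x.g_end - 1 > params.g_insert:
            break
        if _pair_state1(
            x, z, lengths, params, _effective_gap(ordered, ix, iz),
            z.g_start - x.g_end - 1,
        ):
            return LinkState.INSERTED
    return LinkState.NOT_LINKED


def make_state_fn(
    ordered: Sequence[Candidate], library, params: LinkParams = LinkParams()
) -> Callable[[Candidate, Candidate], LinkState]:
    """Bind ``link_state`` to a fixed ordered context (the injectable form
    consumed by :func:`build_chains`)."""

    def state_fn(x: Candidate, y: Candidate) -> LinkState:
        return link_state(x, y, ordered, library, params)

    return state_fn


def build_chains(
    ordered: Sequence[Candidate],
    state_fn: Callable[[Candidate, Candidate], LinkState],
) -> tuple[list[Chain], list[Candidate]]:
    """Greedy left-to-right chain construction over one contig.

    A chain starts at the first unconsumed candidate.  From the chain end x,
    the next unconsumed y extends the chain on state 1; on state 2 it is
    provisionally marked inserted and the scan continues; on state 0 the
    chain closes.  Provisional marks are committed only once a continuation
    actually claims the chain past them — otherwise those candidates are
    released and may start chains of their own in the same pass.
    """
    n = len(ordered)
    consumed = [False] * n
    inserted_ids: list[int] = []
    chains: list[Chain] = []
    for start in range(n):
        if consumed[start]:
            continue
        consumed[start] = True
        member_ids = [start]
        x = start
        pending: list[int] = []
        j = start + 1
        while j < n:
            if consumed[j]:
                j += 1
                continue
            state = state_fn(ordered[x], ordered[j])
            if state == LinkState.LINKED:
                for p in pending:
                    consumed[p] = True
                    inserted_ids.append(p)
                pending = []
                consumed[j] = True
                member_ids.append(j)
                x = j
                j = x + 1
            elif state == LinkState.INSERTED:
                pending.append(j)
                j += 1
            else:
                break
        members = [ordered[k] for k in member_ids]
        chains.append(
            Chain(
                members=members,
                contig_id=members[0].contig_id,
                strand=members[0].strand,
            )
        )
    inserted = [ordered[k] for k in sorted(inserted_ids)]
    return chains, inserted


def _assign_hosts(layers: list[tuple[int, list[Chain]]]) -> None:
    for layer_idx, chains in layers:
        if layer_idx == 1:
            continue
        lower = [
            ch
            for li, chs in layers
            if li < layer_idx
            for ch in chs
        ]
        for chain in chains:
            best: Chain | None = None
            for host in lower:
                if host.contig_id != chain.contig_id:
                    continue
                if host.g_start <= chain.g_start and chain.g_end <= host.g_end:
                    if (
                        best is None
                        or host.layer > best.layer
                        or (host.layer == best.layer and host.g_span < best.g_span)
                    ):
                        best = host
            chain.host = best


def resolve_layers(
    candidates: Iterable[Candidate],
    library,
    params: LinkParams = LinkParams(),
) -> list[tuple[int, list[Chain]]]:
    """Recursively chain candidates into nesting layers.

    Layer 1 chains over all candidates; the candidates marked inserted
    during layer k's pass are re-chained as layer k+1, until a pass marks
    nothing inserted.  Each chain of layer >= 2 records the innermost
    lower-layer chain whose span contains it as its host.
    """
    by_contig: dict[str, list[Candidate]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig_id, []).append(c)
    layer_map: dict[int, list[Chain]] = {}
    for contig in sorted(by_contig):
        pool = sorted(by_contig[contig], key=lambda c: (c.g_start, c.g_end))
        layer = 1
        while pool:
            chains, inserted = build_chains(
                pool, make_state_fn(pool, library, params)
            )
            for ch in chains:
                ch.layer = layer
            layer_map.setdefault(layer, []).extend(chains)
            pool = sorted(inserted, key=lambda c: (c.g_start, c.g_end))
            layer += 1
    layers = [(k, layer_map[k]) for k in sorted(layer_map)]
    _assign_hosts(layers)
    return layers
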