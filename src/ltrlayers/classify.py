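"""Structural typing of chains and per-layer summaries.

A chain's type string spells out its part makeup ("LTR-IN-LTR", "IN-LTR",
"LTR", ...): consecutive members that are continuation-linked halves of one
copy collapse into a single label, while part transitions (and
non-continuing same-part neighbours) emit new labels.  Type strings map onto
five categories: Normal, SoloLTR, Complex (three or more LTRs), Truncated
and Others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .defrag import Candidate
from .linker import Chain, continuation_ok

CATEGORIES = ("Normal", "Truncated", "SoloLTR", "Complex", "Others")


class Category:
    NORMAL = "Normal"
    TRUNCATED = "Truncated"
    SOLO_LTR = "SoloLTR"
    COMPLEX = "Complex"
    OTHERS = "Others"


@dataclass
class Element:
    """A classified, layered element: one chain plus its structural type."""

    chain: Chain
    layer: int
    type_string: str
    category: str
    element_id: str = ""
    host: "Element | None" = None

    @property
    def g_start(self) -> int:
        return self.chain.g_start

    @property
    def g_end(self) -> int:
        return self.chain.g_end

    @property
    def nested(self) -> bool:
        return self.layer >= 2

    def family_string(self) -> str:
        fams = []
        for c in self.chain.members:
            if c.family_id not in fams:
                fams.append(c.family_id)
        return ",".join(fams)


def type_string(chain: Chain, cons_tol: int = 30) -> str:
    """Spell the chain's structural type.

    Members joined by a same-part consensus continuation are halves of one
    copy and collapse into a single label.
    """
    if not chain.members:
        raise ValueError("empty chain")
    labels = [chain.members[0].part]
    for prev, nxt in zip(chain.members, chain.members[1:]):
        if prev.part == nxt.part and continuation_ok(prev, nxt, cons_tol):
            continue
        labels.append(nxt.part)
    if chain.strand == "-":
        labels.reverse()  # report 5'->3' in element orientation
    return "-".join(labels)


def categorize(ts: str) -> str:
    """Map a type string to its structural category.

    LTR-IN-LTR -> Normal; lone LTR -> SoloLTR; alternating strings with >= 3
    LTR labels -> Complex; other alternating partial forms -> Truncated;
    anything else -> Others.
    """
    if not ts:
        raise ValueError("empty type string")
    labels = ts.split("-")
    known = all(lab in ("LTR", "IN") for lab in labels)
    alternating = all(a != b for a, b in zip(labels, labels[1:]))
    if not known or not alternating:
        return Category.OTHERS
    n_ltr = labels.count("LTR")
    if ts == "LTR-IN-LTR":
        return Category.NORMAL
    if ts == "LTR":
        return Category.SOLO_LTR
    if n_ltr >= 3:
        return Category.COMPLEX
    return Category.TRUNCATED


def build_elements(
    layers: list[tuple[int, list[Chain]]], cons_tol: int = 30
) -> list[Element]:
    """Turn resolved layers into classified elements with stable IDs and
    host links mirroring the chains' host links."""
    chains: list[tuple[int, Chain]] = [
        (layer, ch) for layer, chs in layers for ch in chs
    ]
    chains.sort(key=lambda t: (t[1].contig_id, t[1].g_start, t[0], t[1].g_end))
    by_chain: dict[int, Element] = {}
    elements: list[Element] = []
    for i, (layer, ch) in enumerate(chains, start=1):
        ts = type_string(ch, cons_tol)
        elem = Element(
            chain=ch,
            layer=layer,
            type_string=ts,
            category=categorize(ts),
            element_id=f"elem_{i:05d}",
        )
        by_chain[id(ch)] = elem
        elements.append(elem)
    for elem in elements:
        if elem.chain.host is not None:
            elem.host = by_chain.get(id(elem.chain.host))
    return elements


@dataclass
class TypeSummary:
    """Counts per (layer, type string) with category rollups."""

    by_layer_type: dict[tuple[int, str], int]
    by_category: dict[str, int]
    nested_count: int
    total: int
    n_layers: int
    elements: list[Element] = field(default_factory=list)

    def category_counts(self, table1_compat: bool = False) -> dict[str, int]:
        """Category rollup; with ``table1_compat`` the Others count is folded
        into Truncated (matching the headline four-category arithmetic)."""
        counts = dict(self.by_category)
        if table1_compat:
            counts[Category.TRUNCATED] = counts.get(
                Category.TRUNCATED, 0
            ) + counts.pop(Category.OTHERS, 0)
            counts[Category.OTHERS] = 0
        return counts


def summarize(elements: Iterable[Element]) -> TypeSummary:
    elements = list(elements)
    by_layer_type: dict[tuple[int, str], int] = {}
    by_category = {c: 0 for c in CATEGORIES}
    nested = 0
    for e in elements:
        key = (e.layer, e.type_string)
        by_layer_type[key] = by_layer_type.get(key, 0) + 1
        by_category[e.category] += 1
        if e.nested:
            nested += 1
    return TypeSummary(
        by_layer_type=by_layer_type,
        by_category=by_category,
        nested_count=nested,
        total=len(elements),
        n_layers=max((e.layer for e in elements), default=0),
        elements=elements,
    )
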