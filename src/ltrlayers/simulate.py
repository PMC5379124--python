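"""Synthetic genomes with planted LTR retrotransposons and exact alignments.

Plants full-length (LTR-IN-LTR), solo-LTR, complex (three LTRs sharing the
middle one), truncated and internal-only elements into a random background,
optionally nesting them over several layers.  Ground truth (spans split by
nested insertions, layer, type, LTR-pair divergence) is tracked exactly, and
``emit_alignments`` renders it as a RepeatMasker ``.out`` table so the whole
pipeline can be exercised without running an external aligner.

TSDs are generated as identical direct repeats flanking TSD-bearing elements
(they are fixtures for future use; nothing downstream consumes them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classify import categorize
from .formats import (
    Fragment,
    LibraryEntry,
    library_index,
    write_repeatmasker_out,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: element-oriented type strings by planted kind
_TYPE_BY_KIND = {
    "normal": "LTR-IN-LTR",
    "solo": "LTR",
    "complex3": "LTR-IN-LTR-IN-LTR",
    "truncated5": "IN-LTR",
    "truncated3": "LTR-IN",
    "internal": "IN",
}

_TSD_KINDS = {"normal", "solo", "complex3"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Deterministic simulation recipe; ``seed`` fully determines output."""

    seed: int = 0
    genome_length: int = 200_000
    n_families: int = 0  # 0 -> one family per planted element
    n_normal: int = 8
    n_solo: int = 6
    n_complex3: int = 2
    n_truncated5: int = 3
    n_truncated3: int = 3
    n_internal: int = 3
    nest_depth_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    tsd_length_range: tuple[int, int] = (4, 6)
    ltr_length_range: tuple[int, int] = (250, 400)
    in_length_range: tuple[int, int] = (1500, 2500)
    mutation_rate_per_site: float = 0.02
    fragmentation_noise: float = 0.0
    contig_name: str = "chr1"
    #: minimum distance of a nested insertion point from piece boundaries;
    #: keeps every split piece long enough to survive default length filters
    insertion_margin: int = 120

    def __post_init__(self) -> None:
        counts = self.kind_counts()
        if any(v < 0 for v in counts.values()):
            raise ValueError("per-type counts must be non-negative")
        w = self.nest_depth_weights
        if not w or abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ValueError("nest_depth_weights must be non-negative and sum to 1")

    def kind_counts(self) -> dict[str, int]:
        return {
            "normal": self.n_normal,
            "solo": self.n_solo,
            "complex3": self.n_complex3,
            "truncated5": self.n_truncated5,
            "truncated3": self.n_truncated3,
            "internal": self.n_internal,
        }


@dataclass
class SimPiece:
    """One aligned piece of a planted element.

    Coordinates are 0-based half-open while local to an assembly and become
    1-based inclusive (``g_start``/``g_end`` semantics) only in the final
    ``GroundTruth.pieces`` list.
    """

    elem_id: int
    family_id: str
    part: str
    strand: str
    start: int
    end: int
    c_start: int  # 1-based inclusive, forward consensus
    c_end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthElement:
    elem_id: int
    family_id: str
    strand: str
    layer: int
    type_string: str
    kind: str
    spans: list[tuple[int, int]]  # 1-based inclusive genome spans
    ltr_divergences: list[float]
    host_id: int | None = None

    @property
    def category(self) -> str:
        return categorize(self.type_string)


@dataclass
class GroundTruth:
    contig: str
    genome_length: int
    elements: list[TruthElement]
    pieces: list[SimPiece]  # absolute 1-based inclusive (start=g_start, end=g_end)

    def layer_type_counts(self) -> dict[tuple[int, str], int]:
        counts: dict[tuple[int, str], int] = {}
        for e in self.elements:
            key = (e.layer, e.type_string)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def n_layers(self) -> int:
        return max((e.layer for e in self.elements), default=0)


@dataclass
class _Assembly:
    """A growing sequence with the planted pieces it contains (local,
    0-based half-open coordinates)."""

    seq: str
    pieces: list[SimPiece] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` (uniform over the
    three alternative bases)."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _split_piece(p: SimPiece, cut: int) -> tuple[SimPiece, SimPiece]:
    """Split a local piece at position ``cut`` (start < cut < end)."""
    left_len = cut - p.start
    if p.strand == "+":
        left = replace(p, end=cut, c_end=p.c_start + left_len - 1)
        right = replace(p, start=cut, c_start=p.c_start + left_len)
    else:
        left = replace(p, end=cut, c_start=p.c_end - left_len + 1)
        right = replace(p, start=cut, c_end=p.c_end - left_len)
    return left, right


def _insert_assembly(host: _Assembly, child: _Assembly, pos: int) -> None:
    """Splice ``child`` into ``host`` at local position ``pos``, splitting
    and shifting host pieces as needed."""
    block = len(child.seq)
    updated: list[SimPiece] = []
    for p in host.pieces:
        if p.end <= pos:
            updated.append(p)
        elif p.start >= pos:
            updated.append(replace(p, start=p.start + block, end=p.end + block))
        else:
            left, right = _split_piece(p, pos)
            updated.append(left)
            updated.append(replace(right, start=right.start + block, end=right.end + block))
    for p in child.pieces:
        updated.append(replace(p, start=p.start + pos, end=p.end + pos))
    updated.sort(key=lambda p: p.start)
    host.pieces = updated
    host.seq = host.seq[:pos] + child.seq + host.seq[pos:]


def _build_families(cfg: SimConfig, n_elements: int, rng) -> list[tuple[str, str, str]]:
    """Return (family_id, ltr_consensus, in_consensus) tuples."""
    n_fam = cfg.n_families if cfg.n_families > 0 else max(n_elements, 1)
    fams = []
    for i in range(n_fam):
        ltr_len = int(rng.integers(cfg.ltr_length_range[0], cfg.ltr_length_range[1] + 1))
        in_len = int(rng.integers(cfg.in_length_range[0], cfg.in_length_range[1] + 1))
        fams.append((f"Fam{i + 1}", _random_seq(rng, ltr_len), _random_seq(rng, in_len)))
    return fams


def _core_layout(
    kind: str, ltr_len: int, in_len: int, rng
) -> list[tuple[str, int, int]]:
    """Consensus intervals (part, c_start, c_end) making up one planted
    element, in element (5'->3') order."""
    full_ltr = ("LTR", 1, ltr_len)
    full_in = ("IN", 1, in_len)
    if kind == "normal":
        return [full_ltr, full_in, full_ltr]
    if kind == "solo":
        return [full_ltr]
    if kind == "complex3":
        return [full_ltr, full_in, full_ltr, full_in, full_ltr]
    if kind == "truncated3":  # 3' end lost: LTR + IN prefix
        keep = int(rng.integers(300, max(301, in_len - 200)))
        return [full_ltr, ("IN", 1, keep)]
    if kind == "truncated5":  # 5' end lost: IN suffix + LTR
        keep = int(rng.integers(300, max(301, in_len - 200)))
        return [("IN", in_len - keep + 1, in_len), full_ltr]
    if kind == "internal":
        length = int(rng.integers(400, min(800, in_len) + 1))
        start = int(rng.integers(1, in_len - length + 2))
        return [("IN", start, start + length - 1)]
    raise ValueError(f"unknown element kind {kind!r}")


def _build_element(
    elem_id: int,
    kind: str,
    family: tuple[str, str, str],
    strand: str,
    cfg: SimConfig,
    rng,
) -> tuple[_Assembly, list[float]]:
    fam_id, ltr_cons, in_cons = family
    layout = _core_layout(kind, len(ltr_cons), len(in_cons), rng)
    seqs: list[str] = []
    pieces: list[SimPiece] = []
    offset = 0
    for part, cs, ce in layout:
        cons = ltr_cons if part == "LTR" else in_cons
        copy = mutate_sequence(cons[cs - 1 : ce], cfg.mutation_rate_per_site, rng)
        pieces.append(
            SimPiece(
                elem_id=elem_id,
                family_id=fam_id,
                part=part,
                strand="+",
                start=offset,
                end=offset + len(copy),
                c_start=cs,
                c_end=ce,
            )
        )
        seqs.append(copy)
        offset += len(copy)
    seq = "".join(seqs)
    # observed divergence of adjacent LTR copies (dating ground truth)
    ltr_seqs = [seqs[i] for i, (part, _, _) in enumerate(layout) if part == "LTR"]
    divergences = [
        sum(a != b for a, b in zip(s1, s2)) / len(s1)
        for s1, s2 in zip(ltr_seqs, ltr_seqs[1:])
    ]
    if kind in _TSD_KINDS:
        tsd_len = int(
            rng.integers(cfg.tsd_length_range[0], cfg.tsd_length_range[1] + 1)
        )
        tsd = _random_seq(rng, tsd_len)
        seq = tsd + seq + tsd
        pieces = [
            replace(p, start=p.start + tsd_len, end=p.end + tsd_len) for p in pieces
        ]
    if strand == "-":
        length = len(seq)
        seq = revcomp(seq)
        pieces = sorted(
            (
                replace(p, start=length - p.end, end=length - p.start, strand="-")
                for p in pieces
            ),
            key=lambda p: p.start,
        )
    return _Assembly(seq=seq, pieces=pieces), divergences


def _own_insertable_intervals(
    assembly: _Assembly, elem_id: int, margin: int
) -> list[SimPiece]:
    return [
        p
        for p in assembly.pieces
        if p.elem_id == elem_id and p.length >= 2 * margin + 2
    ]


def _assign_layers(n: int, weights: tuple[float, ...], rng) -> list[int]:
    depths = list(range(1, len(weights) + 1))
    drawn = [int(rng.choice(depths, p=list(weights))) for _ in range(n)]
    # remap occupied depths onto contiguous ranks so every layer >= 2 has a
    # populated layer below it
    occupied = sorted(set(drawn))
    rank = {d: i + 1 for i, d in enumerate(occupied)}
    return [rank[d] for d in drawn]


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[LibraryEntry], GroundTruth]:
    """Generate (genome, consensus library, ground truth) for one contig."""
    rng = np.random.default_rng(config.seed)
    kinds = [
        kind for kind, n in config.kind_counts().items() for _ in range(n)
    ]
    n_elements = len(kinds)
    families = _build_families(config, n_elements, rng)
    library = []
    for fam_id, ltr_cons, in_cons in families:
        library.append(LibraryEntry(family_id=fam_id, part="LTR", sequence=ltr_cons))
        library.append(LibraryEntry(family_id=fam_id, part="IN", sequence=in_cons))

    layers = _assign_layers(n_elements, config.nest_depth_weights, rng)
    assemblies: list[_Assembly] = []
    meta: list[TruthElement] = []
    for elem_id, kind in enumerate(kinds):
        family = families[elem_id % len(families)]
        strand = "+" if rng.random() < 0.5 else "-"
        assembly, divergences = _build_element(
            elem_id, kind, family, strand, config, rng
        )
        assemblies.append(assembly)
        meta.append(
            TruthElement(
                elem_id=elem_id,
                family_id=family[0],
                strand=strand,
                layer=layers[elem_id],
                type_string=_TYPE_BY_KIND[kind],
                kind=kind,
                spans=[],
                ltr_divergences=divergences,
            )
        )

    # nest bottom-up: deepest layers are spliced into their hosts first
    margin = config.insertion_margin
    absorbed: set[int] = set()
    for depth in sorted(set(layers), reverse=True):
        if depth == 1:
            continue
        for elem_id in [i for i in range(n_elements) if meta[i].layer == depth]:
            hosts = [
                i
                for i in range(n_elements)
                if meta[i].layer == depth - 1
                and _own_insertable_intervals(assemblies[i], i, margin)
            ]
            if not hosts:
                meta[elem_id].layer = 1  # demote: nothing can host it
                continue
            host_id = int(hosts[rng.integers(0, len(hosts))])
            host = assemblies[host_id]
            targets = _own_insertable_intervals(host, host_id, margin)
            target = targets[rng.integers(0, len(targets))]
            pos = int(rng.integers(target.start + margin, target.end - margin + 1))
            _insert_assembly(host, assemblies[elem_id], pos)
            meta[elem_id].host_id = host_id
            absorbed.add(elem_id)

    top_ids = [i for i in range(n_elements) if i not in absorbed]
    planted_total = sum(len(assemblies[i].seq) for i in top_ids)
    bg_len = config.genome_length - planted_total
    if bg_len < len(top_ids):
        raise ValueError(
            f"planted content ({planted_total} bp) exceeds genome_length "
            f"({config.genome_length} bp)"
        )
    background = _random_seq(rng, bg_len)
    cuts = sorted(
        int(c) for c in rng.choice(bg_len + 1, size=len(top_ids), replace=False)
    ) if top_ids else []

    genome_parts: list[str] = []
    all_pieces: list[SimPiece] = []
    prev_cut = 0
    offset = 0
    for i, top_id in enumerate(top_ids):
        cut = cuts[i]
        genome_parts.append(background[prev_cut:cut])
        offset += cut - prev_cut
        asm = assemblies[top_id]
        genome_parts.append(asm.seq)
        for p in asm.pieces:
            # convert to absolute 1-based inclusive
            all_pieces.append(
                replace(p, start=offset + p.start + 1, end=offset + p.end)
            )
        offset += len(asm.seq)
        prev_cut = cut
    genome_parts.append(background[prev_cut:])
    genome_seq = "".join(genome_parts)
    assert len(genome_seq) == config.genome_length

    all_pieces.sort(key=lambda p: p.start)
    by_elem: dict[int, list[SimPiece]] = {}
    for p in all_pieces:
        by_elem.setdefault(p.elem_id, []).append(p)
    for elem in meta:
        spans: list[tuple[int, int]] = []
        for p in by_elem.get(elem.elem_id, []):
            if spans and p.start == spans[-1][1] + 1:
                spans[-1] = (spans[-1][0], p.end)
            else:
                spans.append((p.start, p.end))
        elem.spans = spans

    truth = GroundTruth(
        contig=config.contig_name,
        genome_length=config.genome_length,
        elements=meta,
        pieces=all_pieces,
    )
    return {config.contig_name: genome_seq}, library, truth


def _maybe_fragment(
    piece: SimPiece, noise: float, rng
) -> list[SimPiece]:
    """Split an absolute piece into abutting (or slightly gapped) records."""
    length = piece.end - piece.start + 1
    if noise <= 0 or length < 240 or rng.random() >= noise:
        return [piece]
    left_len = int(rng.integers(120, length - 120 + 1))
    if piece.strand == "+":
        left = replace(
            piece, end=piece.start + left_len - 1, c_end=piece.c_start + left_len - 1
        )
        right = replace(
            piece, start=piece.start + left_len, c_start=piece.c_start + left_len
        )
    else:
        left = replace(
            piece, end=piece.start + left_len - 1, c_start=piece.c_end - left_len + 1
        )
        right = replace(
            piece, start=piece.start + left_len, c_end=piece.c_end - left_len
        )
    if rng.random() < 0.5:
        gap = int(rng.integers(1, 16))  # within defrag tolerances
        if piece.strand == "+":
            right = replace(right, start=right.start + gap, c_start=right.c_start + gap)
        else:
            right = replace(right, start=right.start + gap, c_end=right.c_end - gap)
    return [left, right]


def emit_alignments(
    genome: dict[str, str],
    library: list[LibraryEntry],
    truth: GroundTruth,
    path=None,
    fragmentation_noise: float = 0.0,
    seed: int = 0,
) -> list[Fragment]:
    """Render the ground truth as RepeatMasker-style alignment records.

    With ``fragmentation_noise`` > 0 pieces are randomly split into abutting
    sub-records (sometimes separated by a small, tolerance-compatible gap) to
    exercise defragmentation.  Divergence columns reflect the mutations
    actually applied.  Writes a ``.out`` file when ``path`` is given and
    returns the fragments.
    """
    rng = np.random.default_rng(seed)
    idx = library_index(library)
    seq = genome[truth.contig]
    fragments: list[Fragment] = []
    for piece in truth.pieces:
        for rec in _maybe_fragment(piece, fragmentation_noise, rng):
            segment = seq[rec.start - 1 : rec.end]
            if rec.strand == "-":
                segment = revcomp(segment)
            cons = idx[(rec.family_id, rec.part)].sequence[rec.c_start - 1 : rec.c_end]
            mismatches = sum(a != b for a, b in zip(segment, cons))
            div = round(100.0 * mismatches / max(len(cons), 1), 1)
            fragments.append(
                Fragment(
                    contig_id=truth.contig,
                    g_start=rec.start,
                    g_end=rec.end,
                    strand=rec.strand,
                    family_id=rec.family_id,
                    part=rec.part,
                    c_start=rec.c_start,
                    c_end=rec.c_end,
                    divergence=div,
                    score=10.0 * (rec.end - rec.start + 1),
                )
            )
    fragments.sort(key=lambda f: (f.contig_id, f.g_start, f.g_end))
    if path is not None:
        write_repeatmasker_out(
            fragments,
            path,
            genome_lengths={c: len(s) for c, s in genome.items()},
            consensus_lengths={k: e.length for k, e in idx.items()},
        )
    return fragments


def write_truth_tsv(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "elem_id\tfamily\tstrand\tlayer\ttype\tcategory\tkind\tspans\t"
            "ltr_divergences\thost_id\n"
        )
        for e in truth.elements:
            spans = ";".join(f"{s}-{t}" for s, t in e.spans)
            divs = ";".join(f"{d:.4f}" for d in e.ltr_divergences) or "."
            host = str(e.host_id) if e.host_id is not None else "."
            fh.write(
                f"{e.elem_id}\t{e.family_id}\t{e.strand}\t{e.layer}\t"
                f"{e.type_string}\t{e.category}\t{e.kind}\t{spans}\t{divs}\t{host}\n"
            )


def write_truth_gff3(truth: GroundTruth, path) -> None:
    lines = ["##gff-version 3"]
    for e in sorted(truth.elements, key=lambda e: (e.spans[0][0] if e.spans else 0)):
        if not e.spans:
            continue
        attrs = [
            f"ID=true_{e.elem_id}",
            f"Name={e.family_id}",
            f"ltr_type={e.type_string}",
            f"layer={e.layer}",
        ]
        if e.host_id is not None:
            attrs.append(f"Parent=true_{e.host_id}")
        lines.append(
            "\t".join(
                [
                    truth.contig,
                    "ltrlayers-sim",
                    "repeat_region",
                    str(e.spans[0][0]),
                    str(e.spans[-1][1]),
                    ".",
                    e.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
        for i, (s, t) in enumerate(e.spans, start=1):
            lines.append(
                "\t".join(
                    [
                        truth.contig,
                        "ltrlayers-sim",
                        "match_part",
                        str(s),
                        str(t),
                        ".",
                        e.strand,
                        ".",
                        f"ID=true_{e.elem_id}.{i};Parent=true_{e.elem_id}",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
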