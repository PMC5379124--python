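"""Readers and writers for the external formats the pipeline touches.

Covers the repeat consensus library (FASTA, ``<family>_LTR`` / ``<family>_IN``
naming), genome FASTA, RepeatMasker ``.out`` alignment tables, GFF3 element
output and the per-layer ``type.num.x`` / ``type.all.x`` summary tables.

All coordinates are 1-based inclusive throughout; minus-strand hits are
normalised at parse time so consensus coordinates always refer to the forward
consensus orientation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

PARTS = ("LTR", "IN")


class LibraryFormatError(ValueError):
    """Raised for malformed consensus library entries."""


class RepeatMaskerParseError(ValueError):
    """Raised when a ``.out`` record cannot be parsed."""


@dataclass(frozen=True)
class LibraryEntry:
    """One consensus sequence: either the LTR or the internal region (IN)
    of a repeat family."""

    family_id: str
    part: str  # "LTR" | "IN"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def name(self) -> str:
        return f"{self.family_id}_{self.part}"


@dataclass(frozen=True)
class Fragment:
    """A single alignment hit of a library consensus against the genome.

    ``c_start``/``c_end`` are forward-consensus coordinates even for
    minus-strand hits (``strand == '-'``).
    """

    contig_id: str
    g_start: int
    g_end: int
    strand: str  # "+" | "-"
    family_id: str
    part: str  # "LTR" | "IN"
    c_start: int
    c_end: int
    divergence: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise ValueError(f"g_start > g_end: {self}")
        if self.c_start > self.c_end:
            raise ValueError(f"c_start > c_end: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.part not in PARTS:
            raise ValueError(f"bad part {self.part!r}")

    @property
    def g_len(self) -> int:
        return self.g_end - self.g_start + 1

    @property
    def c_len(self) -> int:
        return self.c_end - self.c_start + 1

    @property
    def identity(self) -> float:
        return 100.0 - self.divergence


def split_repeat_name(name: str) -> tuple[str, str]:
    """Split ``Osr1_LTR`` into ``("Osr1", "LTR")``; raise if no valid suffix."""
    for part in PARTS:
        suffix = "_" + part
        if name.endswith(suffix) and len(name) > len(suffix):
            return name[: -len(suffix)], part
    raise LibraryFormatError(
        f"repeat name {name!r} lacks an _LTR or _IN suffix"
    )


def parse_library_fasta(path: str | os.PathLike) -> list[LibraryEntry]:
    """Parse a consensus library FASTA.

    Every header must end in ``_LTR`` or ``_IN`` and may contain neither
    whitespace nor ``|``.  Families present with only one of the two parts
    are kept but logged as unpaired.
    """
    entries: list[LibraryEntry] = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description or record.id
        if "|" in header:
            raise LibraryFormatError(
                f"library header {header!r} contains a '|' character"
            )
        if header != record.id:
            # SeqIO puts everything after the first whitespace in description
            raise LibraryFormatError(
                f"library header {header!r} contains whitespace"
            )
        family_id, part = split_repeat_name(record.id)
        entries.append(
            LibraryEntry(family_id=family_id, part=part, sequence=str(record.seq).upper())
        )
    for family in unpaired_families(entries):
        logger.warning("library family %s has only one of _LTR/_IN", family)
    return entries


def unpaired_families(entries: Iterable[LibraryEntry]) -> list[str]:
    parts: dict[str, set[str]] = {}
    for e in entries:
        parts.setdefault(e.family_id, set()).add(e.part)
    return sorted(f for f, p in parts.items() if len(p) < 2)


def library_index(entries: Iterable[LibraryEntry]) -> dict[tuple[str, str], LibraryEntry]:
    """Index a library by ``(family_id, part)``."""
    idx: dict[tuple[str, str], LibraryEntry] = {}
    for e in entries:
        if (e.family_id, e.part) in idx:
            raise LibraryFormatError(f"duplicate library entry {e.name}")
        idx[(e.family_id, e.part)] = e
    return idx


def library_lengths(entries: Iterable[LibraryEntry]) -> dict[tuple[str, str], int]:
    return {k: v.length for k, v in library_index(entries).items()}


def write_library_fasta(entries: Iterable[LibraryEntry], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.name}\n")
            for i in range(0, len(e.sequence), 70):
                fh.write(e.sequence[i : i + 70] + "\n")


def read_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read genome sequences into a ``{contig_id: sequence}`` mapping."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = str(record.seq).upper()
    return genome


def write_genome_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for contig in genome:
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_OUT_HEADER = """\
   SW   perc perc perc  query     position in query              matching  repeat          position in repeat
score   div. del. ins.  sequence  begin end          (left)     repeat    class/family  begin  end    (left)  ID

"""


def _is_record_line(tokens: list[str]) -> bool:
    if not tokens:
        return False
    try:
        float(tokens[0])
    except ValueError:
        return False
    return True


def _strip_paren(tok: str) -> int:
    return int(tok.strip("()"))


def parse_repeatmasker_out(
    path: str | os.PathLike,
    library: Iterable[LibraryEntry] | None = None,
) -> list[Fragment]:
    """Parse a RepeatMasker ``.out`` file into Fragments.

    Accepts both aligned-column and loosely whitespace-separated layouts;
    trailing ID / overlap-star columns are ignored.  ``C`` records (repeat
    columns in ``(left) end begin`` order) are normalised so consensus
    coordinates are forward with ``strand == '-'``.

    When ``library`` is given, hits whose consensus coordinates exceed the
    consensus length are reported via logging (never clamped).
    """
    lengths = library_lengths(library) if library is not None else None
    fragments: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not _is_record_line(tokens):
                continue  # header / blank lines
            if len(tokens) < 14:
                raise RepeatMaskerParseError(
                    f"line {lineno}: expected >= 14 columns, got {len(tokens)}"
                )
            try:
                score = float(tokens[0])
                div = float(tokens[1])
                contig = tokens[4]
                g_start = int(tokens[5])
                g_end = int(tokens[6])
                strand_tok = tokens[8]
                repeat = tokens[9]
                if strand_tok == "+":
                    c_start = int(tokens[11])
                    c_end = int(tokens[12])
                    strand = "+"
                elif strand_tok in ("C", "-"):
                    # C layout: (left) end begin
                    c_end = _strip_paren(tokens[12])
                    c_start = _strip_paren(tokens[13])
                    strand = "-"
                else:
                    raise ValueError(f"bad strand column {strand_tok!r}")
            except (ValueError, IndexError) as exc:
                raise RepeatMaskerParseError(f"line {lineno}: {exc}") from exc
            try:
                family_id, part = split_repeat_name(repeat)
            except LibraryFormatError:
                logger.warning(
                    "line %d: repeat name %r has no _LTR/_IN suffix; skipped",
                    lineno,
                    repeat,
                )
                continue
            frag = Fragment(
                contig_id=contig,
                g_start=g_start,
                g_end=g_end,
                strand=strand,
                family_id=family_id,
                part=part,
                c_start=c_start,
                c_end=c_end,
                divergence=div,
                score=score,
            )
            if lengths is not None:
                clen = lengths.get((family_id, part))
                if clen is not None and frag.c_end > clen:
                    logger.warning(
                        "line %d: %s hit exceeds consensus length (%d > %d)",
                        lineno,
                        repeat,
                        frag.c_end,
                        clen,
                    )
            fragments.append(frag)
    return fragments


def write_repeatmasker_out(
    fragments: Iterable[Fragment],
    path: str | os.PathLike,
    genome_lengths: Mapping[str, int] | None = None,
    consensus_lengths: Mapping[tuple[str, str], int] | None = None,
) -> None:
    """Write Fragments as a canonical RepeatMasker ``.out`` file.

    The inverse of :func:`parse_repeatmasker_out` field-for-field; the
    ``(left)`` columns are filled from the supplied lengths or zero.
    """
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, f in enumerate(fragments, start=1):
            g_left = 0
            if genome_lengths and f.contig_id in genome_lengths:
                g_left = genome_lengths[f.contig_id] - f.g_end
            c_left = 0
            if consensus_lengths and (f.family_id, f.part) in consensus_lengths:
                c_left = consensus_lengths[(f.family_id, f.part)] - f.c_end
            name = f"{f.family_id}_{f.part}"
            score = int(f.score) if float(f.score).is_integer() else f.score
            if f.strand == "+":
                rep_cols = f"{f.c_start:>6} {f.c_end:>6} ({c_left})"
                strand_tok = "+"
            else:
                rep_cols = f"({c_left}) {f.c_end:>6} {f.c_start:>6}"
                strand_tok = "C"
            fh.write(
                f"{score:>6} {f.divergence:4.1f}  0.0  0.0  {f.contig_id:<10}"
                f" {f.g_start:>8} {f.g_end:>8} ({g_left}) {strand_tok} "
                f"{name:<15} LTR/unknown {rep_cols} {i}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(elements, path: str | os.PathLike) -> None:
    """Write classified elements as GFF3.

    One ``repeat_region`` feature per element (attributes: ``ID``,
    ``ltr_type``, ``layer``, ``category`` and ``Parent`` for nested elements)
    with one ``match_part`` child per member candidate.
    """
    lines = ["##gff-version 3"]
    ordered = sorted(elements, key=lambda e: (e.chain.contig_id, e.g_start, e.element_id))
    for elem in ordered:
        attrs = [
            f"ID={_gff_escape(elem.element_id)}",
            f"Name={_gff_escape(elem.family_string())}",
            f"ltr_type={_gff_escape(elem.type_string)}",
            f"layer={elem.layer}",
            f"category={elem.category}",
        ]
        if elem.host is not None:
            attrs.append(f"Parent={_gff_escape(elem.host.element_id)}")
        lines.append(
            "\t".join(
                [
                    elem.chain.contig_id,
                    "ltrlayers",
                    "repeat_region",
                    str(elem.g_start),
                    str(elem.g_end),
                    ".",
                    elem.chain.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
        for i, cand in enumerate(elem.chain.members, start=1):
            cattrs = [
                f"ID={_gff_escape(elem.element_id)}.{i}",
                f"Parent={_gff_escape(elem.element_id)}",
                "Target=%s %d %d"
                % (
                    _gff_escape(f"{cand.family_id}_{cand.part}"),
                    cand.covered[0][0],
                    cand.covered[-1][1],
                ),
            ]
            lines.append(
                "\t".join(
                    [
                        cand.contig_id,
                        "ltrlayers",
                        "match_part",
                        str(cand.g_start),
                        str(cand.g_end),
                        ".",
                        cand.strand,
                        ".",
                        ";".join(cattrs),
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# type.num.x / type.all.x tables
# ---------------------------------------------------------------------------

def write_type_tables(summary, out_dir: str | os.PathLike) -> None:
    """Write per-layer ``type.num.x`` (type -> count) and ``type.all.x``
    (one row per element) tab-separated tables into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    for layer in range(1, summary.n_layers + 1):
        counts = {
            t: c for (lyr, t), c in summary.by_layer_type.items() if lyr == layer
        }
        num_path = os.path.join(out_dir, f"type.num.{layer}")
        with open(num_path, "w") as fh:
            fh.write("type\tcount\n")
            for t in sorted(counts, key=lambda t: (-counts[t], t)):
                fh.write(f"{t}\t{counts[t]}\n")
        all_path = os.path.join(out_dir, f"type.all.{layer}")
        with open(all_path, "w") as fh:
            fh.write(
                "contig\tstart\tend\tstrand\ttype\tcategory\telement_id\t"
                "host_id\tmembers\n"
            )
            layer_elems = sorted(
                (e for e in summary.elements if e.layer == layer),
                key=lambda e: (e.chain.contig_id, e.g_start, e.element_id),
            )
            for e in layer_elems:
                members = ",".join(
                    f"{c.g_start}-{c.g_end}:{c.family_id}_{c.part}"
                    for c in e.chain.members
                )
                host_id = e.host.element_id if e.host is not None else "."
                fh.write(
                    f"{e.chain.contig_id}\t{e.g_start}\t{e.g_end}\t"
                    f"{e.chain.strand}\t{e.type_string}\t{e.category}\t"
                    f"{e.element_id}\t{host_id}\t{members}\n"
                )
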