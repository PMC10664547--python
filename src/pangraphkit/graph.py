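"""Pangenome graph data model, GFA/GAF I/O, path sequences, and statistics.

The graph follows GFA semantics: *segments* carry DNA, *links* are oriented
edges, and *haplotype paths* spell out individual assembled haplotypes as
ordered, oriented traversals of segments.  Path names follow the PanSN
convention ``sample#haplotype#contig``; one sample is designated the
reference and its paths define the coordinate system used for projection.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "Segment",
    "Link",
    "Step",
    "HaplotypePath",
    "PangenomeGraph",
    "GraphStats",
    "ReferenceCoordinate",
    "GraphAlignment",
    "GFAParseError",
    "GraphValidationError",
    "reverse_complement",
    "canonical_link",
    "parse_pansn",
    "parse_gfa",
    "write_gfa",
    "parse_gaf",
    "write_gaf",
    "path_sequence",
    "graph_stats",
    "mean_degree",
    "project_to_reference",
    "path_interval_walk",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DNA_RE = re.compile(r"^[ACGTNacgtn]+$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GFAParseError(ValueError):
    """Malformed GFA/GAF input; message carries the offending line number."""


class GraphValidationError(ValueError):
    """Graph model invariant violated (dangling reference, bad step, ...)."""


@dataclass(frozen=True)
class Segment:
    """A graph node carrying a DNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("segment id must be non-empty")
        if len(self.sequence) < 1 or not _DNA_RE.match(self.sequence):
            raise GraphValidationError(
                f"segment {self.id!r}: sequence must be non-empty A/C/G/T/N"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Link:
    """An oriented edge between two segments (stored canonically)."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str

    def __post_init__(self) -> None:
        if self.from_orient not in "+-" or self.to_orient not in "+-":
            raise GraphValidationError("link orientation must be '+' or '-'")


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def canonical_link(from_id: str, from_orient: str, to_id: str, to_orient: str) -> Link:
    """Canonical form of an oriented edge.

    A link a+->b+ and its reverse-complement traversal b- -> a- denote the
    same edge; the lexicographically smaller of the two tuples is stored so
    the link set has set semantics.
    """
    fwd = (from_id, from_orient, to_id, to_orient)
    rev = (to_id, _flip(to_orient), from_id, _flip(from_orient))
    return Link(*min(fwd, rev))


@dataclass(frozen=True)
class Step:
    """One oriented traversal of a segment inside a path."""

    segment_id: str
    orient: str

    def __post_init__(self) -> None:
        if self.orient not in "+-":
            raise GraphValidationError("step orientation must be '+' or '-'")


def parse_pansn(name: str) -> tuple[str, str, str]:
    """Split a path name into (sample, haplotype, contig).

    Full PanSN names have three '#'-separated fields.  Names without '#'
    (plain FASTA contig names) are treated as sample == contig with
    haplotype "0"; two-field names as sample#contig, haplotype "0".
    """
    parts = name.split("#")
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    if len(parts) == 2:
        return parts[0], "0", parts[1]
    return name, "0", name


@dataclass
class HaplotypePath:
    """A named haplotype walk through the graph."""

    name: str
    steps: tuple[Step, ...]

    @property
    def sample(self) -> str:
        return parse_pansn(self.name)[0]

    @property
    def haplotype(self) -> str:
        return parse_pansn(self.name)[1]

    @property
    def contig(self) -> str:
        return parse_pansn(self.name)[2]


@dataclass
class PangenomeGraph:
    """Segments + links + named haplotype paths with a reference sample."""

    segments: dict[str, Segment] = field(default_factory=dict)
    links: set[Link] = field(default_factory=set)
    paths: dict[str, HaplotypePath] = field(default_factory=dict)
    reference_sample: str = ""

    # -- construction helpers ------------------------------------------------

    def add_segment(self, seg_id: str, sequence: str) -> Segment:
        if seg_id in self.segments:
            raise GraphValidationError(f"duplicate segment id {seg_id!r}")
        seg = Segment(seg_id, sequence)
        self.segments[seg_id] = seg
        return seg

    def add_link(self, from_id: str, from_orient: str, to_id: str, to_orient: str) -> Link:
        link = canonical_link(from_id, from_orient, to_id, to_orient)
        self.links.add(link)
        return link

    def add_path(self, name: str, steps: Sequence[Step | tuple[str, str]]) -> HaplotypePath:
        if name in self.paths:
            raise GraphValidationError(f"duplicate path name {name!r}")
        norm = tuple(s if isinstance(s, Step) else Step(*s) for s in steps)
        path = HaplotypePath(name, norm)
        self.paths[name] = path
        # register the implied edges so path-derived graphs are always valid
        for a, b in zip(norm, norm[1:]):
            self.add_link(a.segment_id, a.orient, b.segment_id, b.orient)
        return path

    # -- queries -------------------------------------------------------------

    def has_link(self, from_id: str, from_orient: str, to_id: str, to_orient: str) -> bool:
        return canonical_link(from_id, from_orient, to_id, to_orient) in self.links

    def reference_paths(self) -> list[HaplotypePath]:
        return [p for p in self.paths.values() if p.sample == self.reference_sample]

    def samples(self) -> list[str]:
        return sorted({p.sample for p in self.paths.values()})

    def validate(self) -> None:
        for link in self.links:
            for sid in (link.from_id, link.to_id):
                if sid not in self.segments:
                    raise GraphValidationError(f"link endpoint {sid!r} is not a segment")
        for path in self.paths.values():
            for step in path.steps:
                if step.segment_id not in self.segments:
                    raise GraphValidationError(
                        f"path {path.name!r} references unknown segment {step.segment_id!r}"
                    )
            for a, b in zip(path.steps, path.steps[1:]):
                if not self.has_link(a.segment_id, a.orient, b.segment_id, b.orient):
                    raise GraphValidationError(
                        f"path {path.name!r}: consecutive steps "
                        f"{a.segment_id}{a.orient},{b.segment_id}{b.orient} have no link"
                    )
        if self.reference_sample and not self.reference_paths():
            raise GraphValidationError(
                f"no path belongs to reference sample {self.reference_sample!r}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PangenomeGraph):
            return NotImplemented
        return (
            self.segments == other.segments
            and self.links == other.links
            and {n: tuple(p.steps) for n, p in self.paths.items()}
            == {n: tuple(p.steps) for n, p in other.paths.items()}
        )


# ---------------------------------------------------------------------------
# GFA I/O
# ---------------------------------------------------------------------------


def _open_text(source: str | Path | TextIO) -> tuple[Iterator[str], bool]:
    if hasattr(source, "read"):
        return iter(source), False  # type: ignore[arg-type]
    return iter(open(source, "rt")), True


def parse_gfa(source: str | Path | TextIO, reference_sample: str = "") -> PangenomeGraph:
    """Parse GFA v1.0 (S/L/P lines) or v1.1 (W lines) into a graph.

    W-line sample/haplotype/contig fields are combined into PanSN path names;
    P-line names are kept verbatim.  Raises :class:`GFAParseError` with the
    line number on malformed input and :class:`GraphValidationError` when a
    path references an unknown segment.
    """
    graph = PangenomeGraph(reference_sample=reference_sample)
    pending_paths: list[tuple[int, str, tuple[Step, ...]]] = []
    lines, close = _open_text(source)
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            try:
                if tag == "H":
                    continue
                elif tag == "S":
                    if len(fields) < 3:
                        raise GFAParseError("S line needs id and sequence")
                    graph.add_segment(fields[1], fields[2])
                elif tag == "L":
                    if len(fields) < 6:
                        raise GFAParseError("L line needs 5 fields plus overlap")
                    if fields[5] not in ("*", "0M"):
                        raise GFAParseError(f"unsupported overlap {fields[5]!r}")
                    graph.add_link(fields[1], fields[2], fields[3], fields[4])
                elif tag == "P":
                    if len(fields) < 3:
                        raise GFAParseError("P line needs name and steps")
                    steps = []
                    for tok in fields[2].split(","):
                        if len(tok) < 2 or tok[-1] not in "+-":
                            raise GFAParseError(f"bad path step {tok!r}")
                        steps.append(Step(tok[:-1], tok[-1]))
                    pending_paths.append((lineno, fields[1], tuple(steps)))
                elif tag == "W":
                    if len(fields) < 7:
                        raise GFAParseError("W line needs 6 fields plus walk")
                    name = f"{fields[1]}#{fields[2]}#{fields[3]}"
                    steps = []
                    for m in re.finditer(r"([><])([^><]+)", fields[6]):
                        steps.append(Step(m.group(2), "+" if m.group(1) == ">" else "-"))
                    if not steps:
                        raise GFAParseError(f"empty walk {fields[6]!r}")
                    pending_paths.append((lineno, name, tuple(steps)))
                # other record types are ignored
            except (GFAParseError, GraphValidationError) as exc:
                raise GFAParseError(f"line {lineno}: {exc}") from None
    finally:
        if close:
            lines.close()  # type: ignore[attr-defined]
    for lineno, name, steps in pending_paths:
        for step in steps:
            if step.segment_id not in graph.segments:
                raise GraphValidationError(
                    f"line {lineno}: path {name!r} references unknown segment "
                    f"{step.segment_id!r}"
                )
        graph.add_path(name, steps)
    graph.validate()
    return graph


def write_gfa(graph: PangenomeGraph, version: str = "1.0") -> str:
    """Serialize a graph as GFA text with deterministic ordering.

    Segments are ordered by id, links lexicographically, paths by name, so
    the same graph always serializes to identical bytes.
    """
    if version not in ("1.0", "1.1"):
        raise ValueError(f"unsupported GFA version {version!r}")
    out = io.StringIO()
    out.write(f"H\tVN:Z:{version}\n")
    for sid in sorted(graph.segments):
        out.write(f"S\t{sid}\t{graph.segments[sid].sequence}\n")
    for link in sorted(graph.links):
        out.write(
            f"L\t{link.from_id}\t{link.from_orient}\t{link.to_id}\t{link.to_orient}\t0M\n"
        )
    for name in sorted(graph.paths):
        path = graph.paths[name]
        if version == "1.0":
            steps = ",".join(f"{s.segment_id}{s.orient}" for s in path.steps)
            out.write(f"P\t{name}\t{steps}\t*\n")
        else:
            sample, hap, contig = parse_pansn(name)
            walk = "".join(
                (">" if s.orient == "+" else "<") + s.segment_id for s in path.steps
            )
            length = sum(len(graph.segments[s.segment_id]) for s in path.steps)
            out.write(f"W\t{sample}\t{hap}\t{contig}\t0\t{length}\t{walk}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Path sequence and statistics
# ---------------------------------------------------------------------------


def path_sequence(graph: PangenomeGraph, path_name: str) -> str:
    """Concatenated sequence of a haplotype path.

    '-' steps contribute the reverse complement of the segment.  A path may
    traverse the same segment multiple times (duplications), in which case
    the repeated sequence is counted each time.
    """
    if path_name not in graph.paths:
        raise KeyError(f"unknown path {path_name!r}")
    parts = []
    for step in graph.paths[path_name].steps:
        seq = graph.segments[step.segment_id].sequence
        parts.append(seq if step.orient == "+" else reverse_complement(seq))
    return "".join(parts)


def mean_degree(n_links: int, n_segments: int) -> float:
    """Edges per node, the convention used for pangenome graph summaries."""
    if n_segments == 0:
        raise ValueError("empty graph has no mean degree")
    return n_links / n_segments


@dataclass
class GraphStats:
    """Graph/path size accounting.

    ``total_length`` is the sum of all segment lengths (sequence stored in
    the graph); ``path_length`` counts repeated traversals, so a haplotype
    with a duplicated block B has path length A + 2B + C while the graph
    holds only A + B + C; ``traversed_length`` per sample is the length of
    the union of segments touched by any of that sample's paths.
    """

    n_segments: int
    n_links: int
    mean_degree: float
    total_length: int
    path_length: dict[str, int]
    traversed_length: dict[str, int]

    def summary_tsv(self) -> str:
        lines = ["metric\tname\tvalue"]
        lines.append(f"n_segments\t.\t{self.n_segments}")
        lines.append(f"n_links\t.\t{self.n_links}")
        lines.append(f"mean_degree\t.\t{round(self.mean_degree, 1)}")
        lines.append(f"total_length\t.\t{self.total_length}")
        for name in sorted(self.path_length):
            lines.append(f"path_length\t{name}\t{self.path_length[name]}")
        for name in sorted(self.traversed_length):
            lines.append(f"traversed_length\t{name}\t{self.traversed_length[name]}")
        return "\n".join(lines) + "\n"


def graph_stats(graph: PangenomeGraph) -> GraphStats:
    """Compute node/edge counts, mean degree, and length accounting."""
    if not graph.segments:
        raise ValueError("empty graph")
    path_length: dict[str, int] = {}
    touched: dict[str, set[str]] = {}
    for name, path in graph.paths.items():
        path_length[name] = sum(len(graph.segments[s.segment_id]) for s in path.steps)
        touched.setdefault(path.sample, set()).update(s.segment_id for s in path.steps)
    traversed = {
        sample: sum(len(graph.segments[sid]) for sid in sids)
        for sample, sids in touched.items()
    }
    return GraphStats(
        n_segments=len(graph.segments),
        n_links=len(graph.links),
        mean_degree=mean_degree(len(graph.links), len(graph.segments)),
        total_length=sum(len(s) for s in graph.segments.values()),
        path_length=path_length,
        traversed_length=traversed,
    )


# ---------------------------------------------------------------------------
# Coordinate projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceCoordinate:
    contig: str
    position: int  # 1-based
    on_reference: bool


def _reference_index(graph: PangenomeGraph) -> dict[str, tuple[str, int, str]]:
    """segment id -> (contig, 1-based start of segment on reference, orient).

    First traversal wins when a reference path loops through a segment.
    """
    index: dict[str, tuple[str, int, str]] = {}
    for path in graph.reference_paths():
        pos = 1
        for step in path.steps:
            if step.segment_id not in index:
                index[step.segment_id] = (path.contig, pos, step.orient)
            pos += len(graph.segments[step.segment_id])
    return index


def project_to_reference(
    graph: PangenomeGraph, segment_id: str, offset: int
) -> ReferenceCoordinate:
    """Project a base (segment, 0-based offset) to reference coordinates.

    Bases on a reference path get their exact 1-based position.  Off-reference
    bases (e.g., inside an insertion) are anchored to the last reference base
    preceding the segment along a haplotype path through it, with
    ``on_reference=False``.
    """
    if segment_id not in graph.segments:
        raise KeyError(f"unknown segment {segment_id!r}")
    seg = graph.segments[segment_id]
    if not 0 <= offset < len(seg):
        raise ValueError(f"offset {offset} outside segment {segment_id!r}")
    index = _reference_index(graph)
    if segment_id in index:
        contig, start, orient = index[segment_id]
        if orient == "+":
            return ReferenceCoordinate(contig, start + offset, True)
        return ReferenceCoordinate(contig, start + len(seg) - 1 - offset, True)
    # walk back along any haplotype path through the segment to the nearest
    # preceding on-reference segment
    for name in sorted(graph.paths):
        steps = graph.paths[name].steps
        for i, step in enumerate(steps):
            if step.segment_id != segment_id:
                continue
            for j in range(i - 1, -1, -1):
                prev = steps[j]
                if prev.segment_id in index:
                    contig, start, _ = index[prev.segment_id]
                    plen = len(graph.segments[prev.segment_id])
                    pos = start + plen - 1 if prev.orient == "+" else start
                    return ReferenceCoordinate(contig, pos, False)
            break  # first occurrence in this path had no reference ancestor
    raise ValueError(f"segment {segment_id!r} is unreachable from any reference path")


def path_interval_walk(
    graph: PangenomeGraph, path_name: str, start: int, end: int
) -> tuple[tuple[Step, ...], int, int]:
    """Steps of a path covering sequence interval [start, end).

    Returns (walk, walk_start, walk_end) where the offsets are 0-based into
    the concatenated sequence of the returned walk.  Used to turn truth read
    origins into graph alignments.
    """
    if path_name not in graph.paths:
        raise KeyError(f"unknown path {path_name!r}")
    if not 0 <= start < end:
        raise ValueError("need 0 <= start < end")
    steps = graph.paths[path_name].steps
    walk: list[Step] = []
    first_offset = None
    pos = 0
    for step in steps:
        seg_len = len(graph.segments[step.segment_id])
        if pos + seg_len > start and pos < end:
            if first_offset is None:
                first_offset = pos
            walk.append(step)
        pos += seg_len
        if pos >= end:
            break
    if first_offset is None or pos < end:
        raise ValueError(f"interval [{start},{end}) outside path {path_name!r}")
    return tuple(walk), start - first_offset, end - first_offset


# ---------------------------------------------------------------------------
# GAF (graph alignment) records
# ---------------------------------------------------------------------------


@dataclass
class GraphAlignment:
    """A GAF-style read-to-graph alignment: oriented walk + offsets + mapq."""

    read_id: str
    walk: tuple[Step, ...]
    path_start: int  # 0-based offset in the walk's concatenated sequence
    path_end: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.walk:
            raise GraphValidationError("alignment walk must be non-empty")
        if not 0 <= self.path_start <= self.path_end:
            raise GraphValidationError("need 0 <= path_start <= path_end")
        if not 0 <= self.mapq <= 60:
            raise GraphValidationError("mapq must be in 0..60")


def _walk_string(walk: Iterable[Step]) -> str:
    return "".join((">" if s.orient == "+" else "<") + s.segment_id for s in walk)


def parse_walk_string(text: str) -> tuple[Step, ...]:
    steps = tuple(
        Step(m.group(2), "+" if m.group(1) == ">" else "-")
        for m in re.finditer(r"([><])([^><]+)", text)
    )
    if not steps:
        raise GFAParseError(f"bad walk string {text!r}")
    return steps


def write_gaf(alignments: Iterable[GraphAlignment], graph: PangenomeGraph) -> str:
    """Serialize alignments as tab-separated GAF records."""
    out = io.StringIO()
    for aln in alignments:
        plen = sum(len(graph.segments[s.segment_id]) for s in aln.walk)
        qlen = aln.path_end - aln.path_start
        out.write(
            "\t".join(
                [
                    aln.read_id,
                    str(qlen),
                    "0",
                    str(qlen),
                    "+",
                    _walk_string(aln.walk),
                    str(plen),
                    str(aln.path_start),
                    str(aln.path_end),
                    str(qlen),
                    str(qlen),
                    str(aln.mapq),
                ]
            )
            + "\n"
        )
    return out.getvalue()


def parse_gaf(source: str | Path | TextIO) -> list[GraphAlignment]:
    """Parse GAF records (walk strings of the form '>id<id...')."""
    lines, close = _open_text(source)
    alignments = []
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GFAParseError(f"line {lineno}: GAF record needs 12 fields")
            try:
                alignments.append(
                    GraphAlignment(
                        read_id=fields[0],
                        walk=parse_walk_string(fields[5]),
                        path_start=int(fields[7]),
                        path_end=int(fields[8]),
                        mapq=int(fields[11]),
                    )
                )
            except (ValueError, GraphValidationError) as exc:
                raise GFAParseError(f"line {lineno}: {exc}") from None
    finally:
        if close:
            lines.close()  # type: ignore[attr-defined]
    return alignments
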