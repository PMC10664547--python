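"""Structural-variant analysis on the graph and from graph alignments.

Two complementary views of complex SVs such as the K feathering locus:

* **Path coverage** — the number of times a haplotype path passes through a
  node.  Coverage >= 2 on a run of nodes indicates a duplication in that
  haplotype (assembly-level evidence).
* **Edge support** — for read-level genotyping, each declared event names
  diagnostic *presence* and *absence* junction edges; reads covering at
  least one base on each side of a junction support its edge.  Genotypes
  are assigned by two exact binomial tests at level alpha: the call is
  *present* when the presence hypothesis is retained and the absence
  hypothesis rejected, *absent* in the reverse case, and *inconclusive*
  when both are retained or both rejected.  Events are modeled with an
  expected presence-edge read fraction theta_present (≈1-ε for a simple
  insertion; 0.5 for a hemizygous tandem duplication whose carrier walks
  both the loop-back and the exit edge once) and a noise fraction
  theta_absent (ε) under the absent genotype.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from .graph import (
    GraphAlignment,
    Link,
    PangenomeGraph,
    canonical_link,
    project_to_reference,
)

__all__ = [
    "PathCoverage",
    "DuplicationRun",
    "SVEventModel",
    "EdgeSupport",
    "SVCall",
    "node_path_coverage",
    "detect_duplications",
    "count_edge_support",
    "genotype_sv",
    "k_locus_event_models",
    "load_event_models",
    "dump_event_models",
]

PRESENT = "present"
ABSENT = "absent"
INCONCLUSIVE = "inconclusive"
NO_DATA = "no_data"


@dataclass
class PathCoverage:
    """Traversal counts per (segment, path)."""

    counts: dict[tuple[str, str], int]

    def get(self, segment_id: str, path_name: str) -> int:
        return self.counts.get((segment_id, path_name), 0)

    def path_total_bp(self, graph: PangenomeGraph, path_name: str) -> int:
        """Sum of count x segment length for a path; equals its path length."""
        return sum(
            c * len(graph.segments[sid])
            for (sid, name), c in self.counts.items()
            if name == path_name
        )


def node_path_coverage(graph: PangenomeGraph) -> PathCoverage:
    """Exact traversal counts of every segment by every path."""
    counter: Counter[tuple[str, str]] = Counter()
    for name, path in graph.paths.items():
        for step in path.steps:
            counter[(step.segment_id, name)] += 1
    return PathCoverage(dict(counter))


@dataclass
class DuplicationRun:
    path: str
    segments: tuple[str, ...]
    ref_contig: str
    ref_start: int  # 1-based inclusive
    ref_end: int  # 1-based inclusive
    max_count: int


def detect_duplications(
    coverage: PathCoverage, graph: PangenomeGraph, min_count: int = 2
) -> list[DuplicationRun]:
    """Maximal runs of reference-ordered segments with coverage >= min_count.

    Runs are reported per path with their projected reference interval; two
    disjoint duplications yield two runs.
    """
    ref_order: list[str] = []
    seen: set[str] = set()
    for ref_path in graph.reference_paths():
        for step in ref_path.steps:
            if step.segment_id not in seen:
                seen.add(step.segment_id)
                ref_order.append(step.segment_id)
    runs: list[DuplicationRun] = []
    for name in sorted(graph.paths):
        current: list[str] = []
        best = 0

        def flush() -> None:
            nonlocal current, best
            if current:
                start = project_to_reference(graph, current[0], 0)
                last_len = len(graph.segments[current[-1]])
                end = project_to_reference(graph, current[-1], last_len - 1)
                runs.append(
                    DuplicationRun(
                        path=name,
                        segments=tuple(current),
                        ref_contig=start.contig,
                        ref_start=min(start.position, end.position),
                        ref_end=max(start.position, end.position),
                        max_count=best,
                    )
                )
            current, best = [], 0

        for sid in ref_order:
            c = coverage.get(sid, name)
            if c >= min_count:
                current.append(sid)
                best = max(best, c)
            else:
                flush()
        flush()
    return runs


# ---------------------------------------------------------------------------
# Event models and edge support
# ---------------------------------------------------------------------------


@dataclass
class SVEventModel:
    """A complex SV event genotypable from diagnostic junction edges.

    Multi-edge sides (e.g., an insertion requiring both its entry and exit
    junction) use the minimum per-edge read count — the bottleneck rule.
    """

    name: str
    presence_edges: tuple[Link, ...]
    absence_edges: tuple[Link, ...]
    theta_present: float = 0.98
    theta_absent: float = 0.02
    alpha: float = 0.05
    min_reads: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.theta_absent < self.theta_present < 1:
            raise ValueError("need 0 < theta_absent < theta_present < 1")
        if not self.presence_edges or not self.absence_edges:
            raise ValueError("event needs at least one edge on each side")


@dataclass
class EdgeSupport:
    event: str
    k_presence: int
    k_absence: int
    per_edge: dict[Link, int] = field(default_factory=dict)
    n_skipped: int = 0


def _read_edges(aln: GraphAlignment, graph: PangenomeGraph) -> set[Link] | None:
    """Canonical edges whose junction the aligned interval straddles.

    A read supports an edge iff its walk contains the oriented segment pair
    and the alignment covers >= 1 base on each side of the junction; a read
    ending exactly at the junction does not support it.  Returns None when
    the walk names an unknown segment.
    """
    edges: set[Link] = set()
    cum = 0
    for a, b in zip(aln.walk, aln.walk[1:]):
        if a.segment_id not in graph.segments or b.segment_id not in graph.segments:
            return None
        cum += len(graph.segments[a.segment_id])
        if aln.path_start < cum < aln.path_end:
            edges.add(canonical_link(a.segment_id, a.orient, b.segment_id, b.orient))
    if aln.walk and aln.walk[-1].segment_id not in graph.segments:
        return None
    return edges


def count_edge_support(
    alignments: Iterable[GraphAlignment],
    events: Sequence[SVEventModel],
    graph: PangenomeGraph,
) -> dict[str, EdgeSupport]:
    """Count reads supporting each event's diagnostic edges.

    Each read counts at most once per edge.  Reads whose walks name unknown
    segments are skipped and tallied in ``n_skipped``.
    """
    wanted: set[Link] = set()
    for ev in events:
        wanted.update(ev.presence_edges)
        wanted.update(ev.absence_edges)
    edge_counts: Counter[Link] = Counter()
    n_skipped = 0
    for aln in alignments:
        edges = _read_edges(aln, graph)
        if edges is None:
            n_skipped += 1
            continue
        for edge in edges & wanted:
            edge_counts[edge] += 1
    out: dict[str, EdgeSupport] = {}
    for ev in events:
        per_edge = {e: edge_counts.get(e, 0) for e in (*ev.presence_edges, *ev.absence_edges)}
        out[ev.name] = EdgeSupport(
            event=ev.name,
            k_presence=min(edge_counts.get(e, 0) for e in ev.presence_edges),
            k_absence=min(edge_counts.get(e, 0) for e in ev.absence_edges),
            per_edge=per_edge,
            n_skipped=n_skipped,
        )
    return out


@dataclass
class SVCall:
    event: str
    sample: str
    k_presence: int
    k_absence: int
    p_present: float | None
    p_absent: float | None
    call: str


def genotype_sv(
    support: EdgeSupport, model: SVEventModel, sample: str = ""
) -> SVCall:
    """Two-hypothesis binomial genotype call from edge-support counts.

    With n = k_presence + k_absence informative reads, exact two-sided
    binomial p-values are computed for k_presence under theta_present and
    theta_absent.  Below ``min_reads`` the call is ``no_data`` (absence of
    evidence, not evidence of absence).
    """
    k, n = support.k_presence, support.k_presence + support.k_absence
    if n < model.min_reads:
        return SVCall(model.name, sample, support.k_presence, support.k_absence,
                      None, None, NO_DATA)
    p_present = binomtest(k, n, model.theta_present).pvalue
    p_absent = binomtest(k, n, model.theta_absent).pvalue
    if p_present > model.alpha and p_absent <= model.alpha:
        call = PRESENT
    elif p_absent > model.alpha and p_present <= model.alpha:
        call = ABSENT
    else:
        call = INCONCLUSIVE
    return SVCall(model.name, sample, support.k_presence, support.k_absence,
                  p_present, p_absent, call)


# ---------------------------------------------------------------------------
# K-locus models and event-model (de)serialization
# ---------------------------------------------------------------------------


def k_locus_event_models(
    edges: Mapping[str, Link],
    alpha: float = 0.05,
    min_reads: int = 4,
    noise: float = 0.02,
) -> list[SVEventModel]:
    """The two K-locus events over the labeled edge map e1..e7.

    The element insertion is supported by its entry/exit junctions (e6, e7)
    against the skip edge (e5).  The tandem duplication is supported by the
    loop-back junctions (e3, e4) against the exit edge (e2) with
    theta_present = 0.5, because a hemizygous late-feathering chromosome
    traverses the loop-back and the exit once each.
    """
    return [
        SVEventModel(
            name="ev21_insertion",
            presence_edges=(edges["e6"], edges["e7"]),
            absence_edges=(edges["e5"],),
            theta_present=1 - noise,
            theta_absent=noise,
            alpha=alpha,
            min_reads=min_reads,
        ),
        SVEventModel(
            name="tandem_duplication",
            presence_edges=(edges["e3"], edges["e4"]),
            absence_edges=(edges["e2"],),
            theta_present=0.5,
            theta_absent=noise,
            alpha=alpha,
            min_reads=min_reads,
        ),
    ]


def _link_to_list(link: Link) -> list[str]:
    return [link.from_id, link.from_orient, link.to_id, link.to_orient]


def dump_event_models(events: Sequence[SVEventModel]) -> str:
    payload = [
        {
            "name": ev.name,
            "presence_edges": [_link_to_list(e) for e in ev.presence_edges],
            "absence_edges": [_link_to_list(e) for e in ev.absence_edges],
            "theta_present": ev.theta_present,
            "theta_absent": ev.theta_absent,
            "alpha": ev.alpha,
            "min_reads": ev.min_reads,
        }
        for ev in events
    ]
    return json.dumps(payload, indent=2) + "\n"


def load_event_models(source: str | Path | list) -> list[SVEventModel]:
    """Load event models from a JSON/YAML file path or a parsed list."""
    if isinstance(source, list):
        payload = source
    else:
        text = Path(source).read_text()
        try:
            payload = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            payload = yaml.safe_load(text)
    out = []
    for item in payload:
        out.append(
            SVEventModel(
                name=item["name"],
                presence_edges=tuple(canonical_link(*e) for e in item["presence_edges"]),
                absence_edges=tuple(canonical_link(*e) for e in item["absence_edges"]),
                theta_present=float(item.get("theta_present", 0.98)),
                theta_absent=float(item.get("theta_absent", 0.02)),
                alpha=float(item.get("alpha", 0.05)),
                min_reads=int(item.get("min_reads", 4)),
            )
        )
    return out
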