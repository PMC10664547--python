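"""Short-read simulation with an error model, and alignment scoring.

Paired-end reads are sampled uniformly along haplotype path sequences
(paths weighted by length), then substitution and indel errors are injected
per base.  The defaults follow empirical Illumina-style error estimates: a
substitution rate of 0.24% and an indel event rate of 0.029% per base, with
geometric indel lengths.  Truth origins (pre-error coordinates) are kept for
every mate so alignment correctness can be scored as a function of the
mapping-quality threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph import (
    GraphAlignment,
    PangenomeGraph,
    path_interval_walk,
    path_sequence,
    project_to_reference,
    reverse_complement,
)

__all__ = [
    "ErrorModel",
    "SimulatedRead",
    "ReadPair",
    "ReadSet",
    "AccuracyCurve",
    "AlignedRead",
    "simulate_reads",
    "evaluate_alignments",
    "truth_graph_alignments",
    "truth_to_reference",
    "sam_to_aligned",
    "gaf_to_aligned",
]

_BASES = "ACGT"
_QUAL_CHAR = "?"  # constant Q30 placeholder; downstream stages ignore quality


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error probabilities for read simulation."""

    sub_rate: float = 0.0024
    indel_rate: float = 0.00029
    indel_geom_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate < 0.5 and 0 <= self.indel_rate < 0.5):
            raise ValueError("error rates must be in [0, 0.5)")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    path: str
    start: int  # 0-based pre-error origin on the path sequence
    strand: str  # + or -
    n_subs: int = 0
    n_indel_events: int = 0


@dataclass
class ReadPair:
    mate1: SimulatedRead
    mate2: SimulatedRead
    fragment_length: int


@dataclass
class ReadSet:
    pairs: list[ReadPair]
    read_len: int
    error_model: ErrorModel

    def reads(self) -> Iterable[SimulatedRead]:
        for pair in self.pairs:
            yield pair.mate1
            yield pair.mate2

    @property
    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads())

    @property
    def total_subs(self) -> int:
        return sum(r.n_subs for r in self.reads())

    @property
    def total_indel_events(self) -> int:
        return sum(r.n_indel_events for r in self.reads())

    def fastq(self) -> tuple[str, str]:
        out1, out2 = io.StringIO(), io.StringIO()
        for pair in self.pairs:
            for out, mate in ((out1, pair.mate1), (out2, pair.mate2)):
                out.write(
                    f"@{mate.read_id}\n{mate.sequence}\n+\n"
                    f"{_QUAL_CHAR * len(mate.sequence)}\n"
                )
        return out1.getvalue(), out2.getvalue()

    def truth_tsv(self) -> str:
        lines = ["read_id\tpath\tstart\tstrand"]
        for r in self.reads():
            lines.append(f"{r.read_id}\t{r.path}\t{r.start}\t{r.strand}")
        return "\n".join(lines) + "\n"


def _apply_errors(
    template: str, read_len: int, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, int, int] | None:
    """Inject errors while copying ``template`` into a read of ``read_len``.

    Returns (sequence, n_subs, n_indel_events), or None when the template is
    exhausted before the read is complete (caller resamples).
    """
    out: list[str] = []
    i = 0
    subs = events = 0
    while len(out) < read_len:
        if i >= len(template):
            return None
        if model.indel_rate and rng.random() < model.indel_rate:
            events += 1
            length = int(rng.geometric(model.indel_geom_p))
            if rng.random() < 0.5:  # insertion of random bases
                for _ in range(length):
                    if len(out) < read_len:
                        out.append(_BASES[rng.integers(0, 4)])
            else:  # deletion: skip template bases
                i += length
            continue
        base = template[i]
        i += 1
        if model.sub_rate and rng.random() < model.sub_rate:
            choices = [b for b in _BASES if b != base]
            base = choices[rng.integers(0, 3)]
            subs += 1
        out.append(base)
    return "".join(out), subs, events


def simulate_reads(
    graph: PangenomeGraph,
    path_names: Sequence[str] | None = None,
    n_pairs: int = 1000,
    read_len: int = 150,
    fragment_mean: float = 400.0,
    fragment_sd: float = 60.0,
    error_model: ErrorModel = ErrorModel(),
    seed: int = 0,
) -> ReadSet:
    """Simulate paired-end reads from haplotype path sequences.

    Fragment starts are uniform over valid positions of the selected path,
    paths weighted by length; fragments overlapping path ends are resampled
    rather than clipped so truth origins stay unambiguous.  Identical inputs
    and seed produce identical output.
    """
    rng = np.random.default_rng(seed)
    names = list(path_names) if path_names is not None else sorted(graph.paths)
    seqs = {n: path_sequence(graph, n) for n in names}
    min_len = int(max(read_len, fragment_mean))
    eligible = [n for n in names if len(seqs[n]) >= min_len]
    if not eligible:
        raise ValueError("no path is long enough for the requested fragments")
    weights = np.array([len(seqs[n]) for n in eligible], dtype=float)
    weights /= weights.sum()
    margin = 50
    pairs: list[ReadPair] = []
    for k in range(n_pairs):
        while True:
            name = eligible[rng.choice(len(eligible), p=weights)]
            seq = seqs[name]
            plen = len(seq)
            frag = int(round(rng.normal(fragment_mean, fragment_sd)))
            frag = max(read_len, min(frag, plen))
            start = int(rng.integers(0, plen - frag + 1))
            flip = rng.random() < 0.5
            fwd_start = start
            rev_start = start + frag - read_len
            fwd_template = seq[fwd_start : min(plen, fwd_start + read_len + margin)]
            rseq = reverse_complement(seq)
            r0 = plen - (start + frag)
            rev_template = rseq[r0 : min(plen, r0 + read_len + margin)]
            made_f = _apply_errors(fwd_template, read_len, error_model, rng)
            made_r = _apply_errors(rev_template, read_len, error_model, rng)
            if made_f is None or made_r is None:
                continue
            fwd = SimulatedRead("", made_f[0], name, fwd_start, "+", made_f[1], made_f[2])
            rev = SimulatedRead("", made_r[0], name, rev_start, "-", made_r[1], made_r[2])
            m1, m2 = (rev, fwd) if flip else (fwd, rev)
            m1.read_id = f"r{k:06d}/1"
            m2.read_id = f"r{k:06d}/2"
            pairs.append(ReadPair(m1, m2, frag))
            break
    return ReadSet(pairs=pairs, read_len=read_len, error_model=error_model)


# ---------------------------------------------------------------------------
# Truth-derived graph alignments (an "oracle aligner" for downstream stages)
# ---------------------------------------------------------------------------


def truth_graph_alignments(
    graph: PangenomeGraph, read_set: ReadSet, mapq: int = 60
) -> list[GraphAlignment]:
    """Perfect graph alignments at each read's truth origin.

    The read's pre-error interval on its source path is converted to an
    oriented node walk with offsets — the GAF-shaped input that edge-support
    genotyping consumes.  Alignment itself is out of scope; these records
    stand in for an aligner on simulated data.
    """
    out = []
    for read in read_set.reads():
        walk, ws, we = path_interval_walk(
            graph, read.path, read.start, read.start + read_set.read_len
        )
        out.append(GraphAlignment(read.read_id, walk, ws, we, mapq=mapq))
    return out


# ---------------------------------------------------------------------------
# Alignment accuracy
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """One read's alignment in linear coordinates (from SAM or projected GAF)."""

    read_id: str
    ref_name: str
    start: int  # 0-based
    mapq: int
    mapped: bool = True


@dataclass
class AccuracyCurve:
    """Fraction of ALL simulated reads mapped correctly at mapq >= t, t=0..60.

    Unmapped and missing reads count as incorrect at every threshold, so the
    curve is monotone non-increasing in the threshold.
    """

    fractions: tuple[float, ...]
    n_reads: int
    n_missing: int = 0

    def at(self, threshold: int) -> float:
        return self.fractions[threshold]

    def to_tsv(self) -> str:
        lines = ["mapq_threshold\tfraction_correct"]
        for t, f in enumerate(self.fractions):
            lines.append(f"{t}\t{f:.6f}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TruthPosition:
    read_id: str
    ref_name: str
    start: int  # 0-based


def truth_positions(read_set: ReadSet) -> list[TruthPosition]:
    """Truth origins keyed the way alignments report them (path coordinates)."""
    return [TruthPosition(r.read_id, r.path, r.start) for r in read_set.reads()]


def truth_to_reference(
    graph: PangenomeGraph, read_set: ReadSet
) -> list[TruthPosition]:
    """Truth origins projected to reference-path coordinates.

    Lets linear (SAM) alignments against the reference be scored against
    reads simulated from non-reference haplotypes.
    """
    prefix_cache: dict[str, list[int]] = {}
    out = []
    for read in read_set.reads():
        steps = graph.paths[read.path].steps
        if read.path not in prefix_cache:
            acc = [0]
            for s in steps:
                acc.append(acc[-1] + len(graph.segments[s.segment_id]))
            prefix_cache[read.path] = acc
        prefix = prefix_cache[read.path]
        idx = int(np.searchsorted(prefix, read.start, side="right")) - 1
        step = steps[idx]
        within = read.start - prefix[idx]
        if step.orient == "-":
            within = len(graph.segments[step.segment_id]) - 1 - within
        coord = project_to_reference(graph, step.segment_id, within)
        out.append(TruthPosition(read.read_id, coord.contig, coord.position - 1))
    return out


def sam_to_aligned(sam_path) -> list[AlignedRead]:
    """Load primary alignments from a SAM/BAM file as :class:`AlignedRead`.

    Mate ids get the same ``/1``/``/2`` suffixes the simulator writes.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            suffix = "/1" if rec.is_read1 else "/2" if rec.is_read2 else ""
            name = rec.query_name or ""
            if name.endswith(("/1", "/2")):
                suffix = ""
            out.append(
                AlignedRead(
                    read_id=name + suffix,
                    ref_name=rec.reference_name or "",
                    start=rec.reference_start if not rec.is_unmapped else -1,
                    mapq=rec.mapping_quality,
                    mapped=not rec.is_unmapped,
                )
            )
    return out


def gaf_to_aligned(
    alignments: Iterable[GraphAlignment], graph: PangenomeGraph
) -> list[AlignedRead]:
    """Project graph alignments to reference coordinates via their first base."""
    out = []
    for aln in alignments:
        cum = 0
        seg_id, within = None, 0
        for step in aln.walk:
            seg_len = len(graph.segments[step.segment_id])
            if cum + seg_len > aln.path_start:
                within = aln.path_start - cum
                if step.orient == "-":
                    within = seg_len - 1 - within
                seg_id = step.segment_id
                break
            cum += seg_len
        if seg_id is None:
            continue
        coord = project_to_reference(graph, seg_id, within)
        out.append(
            AlignedRead(aln.read_id, coord.contig, coord.position - 1, aln.mapq)
        )
    return out


def evaluate_alignments(
    truth: Sequence[TruthPosition],
    alignments: Iterable[AlignedRead],
    tolerance_bp: int = 100,
) -> AccuracyCurve:
    """Score alignments against truth origins over mapq thresholds 0..60.

    A read is correct iff it is mapped to the same contig/path and its start
    is within ``tolerance_bp`` of the truth start.  The curve denominator is
    all truth reads; reads missing from the alignment set are tallied in
    ``n_missing`` and scored incorrect.
    """
    by_id: dict[str, AlignedRead] = {}
    for aln in alignments:
        by_id.setdefault(aln.read_id, aln)
    correct_mapqs = []
    n_missing = 0
    for t in truth:
        aln = by_id.get(t.read_id)
        if aln is None:
            n_missing += 1
            continue
        if (
            aln.mapped
            and aln.ref_name == t.ref_name
            and abs(aln.start - t.start) <= tolerance_bp
        ):
            correct_mapqs.append(aln.mapq)
    n = len(truth)
    if n == 0:
        raise ValueError("empty truth set")
    mq = np.array(correct_mapqs, dtype=int)
    fractions = tuple(float((mq >= t).sum()) / n for t in range(61))
    return AccuracyCurve(fractions=fractions, n_reads=n, n_missing=n_missing)
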