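"""Seeded synthetic pangenomes with a known variant truth set.

The generator emulates the structure of a multi-haplotype pangenome graph:
one linear reference path plus alternate haplotype paths deviating at SNVs,
small indels, large insertions (optionally with nested SNVs), deletions,
tandem duplications, and a fixed-length mobile-element insertion standing in
for an endogenous retrovirus such as ev21.  Every variant is realized as a
minimal bubble (shared flanks merged maximally), and the same variants are
recorded as a truth set that can be serialized as VCF and used to
reconstruct each haplotype by direct string editing — an oracle that is
independent of the graph construction.

A dedicated fixture models the K feathering locus: a tandem duplication
(late-feathering, LF) and a ~7.5 kb element insertion (ev21+) realized as
separately genotypable junction-edge events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Link, PangenomeGraph, canonical_link, path_sequence, write_gfa
from .catalog import INS, DEL, SNV, VariantRecord, normalize_variant, write_vcf

__all__ = [
    "SVEventSpec",
    "SimConfig",
    "TruthSet",
    "SimResult",
    "GenerationError",
    "generate_pangenome",
    "KLocusFixture",
    "build_k_locus_fixture",
    "K_GENOTYPES",
]

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Event placement failed within the retry bound, or bad configuration."""


@dataclass(frozen=True)
class SVEventSpec:
    """One structural event to place on the reference.

    ``carriers`` may be an explicit tuple of haplotype path names, an integer
    carrier count (random carriers drawn), or None (random count and
    carriers).  ``nested_snvs`` only applies to INS/ELEMENT_INS; the nested
    SNVs are carried by a strict minority subset of the insertion carriers
    so the base insertion sequence is the majority allele.
    """

    kind: str  # INS | DEL | DUP | ELEMENT_INS
    length: int = 0  # ignored for ELEMENT_INS (fixed element length)
    carriers: tuple[str, ...] | int | None = None
    nested_snvs: int = 0


@dataclass
class SimConfig:
    seed: int = 0
    ref_length: int = 10_000
    n_haplotypes: int = 6  # total, including the reference haplotype
    snv_rate: float = 1e-3
    small_indel_rate: float = 1e-4
    indel_geom_p: float = 0.5
    structural_events: tuple[SVEventSpec, ...] = ()
    sample_names: tuple[str, ...] | None = None
    contig: str = "chr1"
    ref_sample: str = "ref"
    element_length: int = 7_500  # stand-in for the >7 kb ev21 element

    def validate(self) -> None:
        if not 0 <= self.snv_rate <= 1 or not 0 <= self.small_indel_rate <= 1:
            raise GenerationError("rates must be in [0, 1]")
        if self.n_haplotypes < 2:
            raise GenerationError("need at least a reference and one haplotype")
        if not 0 < self.indel_geom_p <= 1:
            raise GenerationError("indel_geom_p must be in (0, 1]")
        for ev in self.structural_events:
            if ev.kind not in ("INS", "DEL", "DUP", "ELEMENT_INS"):
                raise GenerationError(f"unknown event kind {ev.kind!r}")
            if ev.nested_snvs and ev.kind not in ("INS", "ELEMENT_INS"):
                raise GenerationError("nested SNVs only allowed inside insertions")

    def hap_path_names(self) -> list[str]:
        """PanSN names of the alternate haplotype paths."""
        n_alt = self.n_haplotypes - 1
        samples = list(self.sample_names or [])
        if len(samples) < n_alt:
            samples += [f"S{i:02d}" for i in range(len(samples) + 1, n_alt + 1)]
        samples = samples[:n_alt]
        names, seen = [], {}
        for s in samples:
            seen[s] = seen.get(s, 0) + 1
            names.append(f"{s}#{seen[s]}#{self.contig}")
        return names

    @property
    def ref_path_name(self) -> str:
        return f"{self.ref_sample}#0#{self.contig}"


@dataclass
class TruthSet:
    """Ground-truth variants of a generated pangenome."""

    records: list[VariantRecord]
    ref_seq: str
    contig: str
    ref_path: str
    hap_paths: list[str]

    def to_vcf(self) -> str:
        samples = [self.ref_path] + self.hap_paths
        return write_vcf(
            self.records, samples, contig_lengths={self.contig: len(self.ref_seq)}
        )

    def reconstruct(self, hap_name: str) -> str:
        """Rebuild a haplotype sequence by editing the reference string.

        Pure string surgery on the truth records — independent of the graph
        realization, so it cross-checks both the generator and the caller.
        """
        edits: list[tuple[int, str, str]] = []
        children: dict[str, list[VariantRecord]] = {}
        for rec in self.records:
            if rec.parent is not None:
                children.setdefault(rec.parent, []).append(rec)
        for rec in self.records:
            if rec.parent is not None:
                continue
            g = rec.genotypes.get(hap_name)
            if g in (None, 0):
                continue
            allele = rec.alts[g - 1]
            if g == 1:
                for child in children.get(rec.id, []):
                    cg = child.genotypes.get(hap_name)
                    if cg in (None, 0):
                        continue
                    if child.kind != SNV:
                        raise GenerationError("only nested SNVs are supported")
                    o = child.pos  # 1-based offset in inserted seq = index in allele
                    if allele[o] != child.ref:
                        raise GenerationError("nested truth inconsistent with parent")
                    allele = allele[:o] + child.alts[cg - 1] + allele[o + 1 :]
            edits.append((rec.pos, rec.ref, allele))
        seq = self.ref_seq
        for pos, ref, allele in sorted(edits, reverse=True):
            if seq[pos - 1 : pos - 1 + len(ref)] != ref:
                raise GenerationError(f"truth ref allele mismatch at {pos}")
            seq = seq[: pos - 1] + allele + seq[pos - 1 + len(ref) :]
        return seq


@dataclass
class SimResult:
    config: SimConfig
    graph: PangenomeGraph
    truth: TruthSet
    haplotypes: dict[str, str]  # path name -> sequence (includes the reference)

    def fasta(self) -> str:
        out = []
        for name in sorted(self.haplotypes):
            out.append(f">{name}\n{self.haplotypes[name]}\n")
        return "".join(out)

    def gfa(self, version: str = "1.1") -> str:
        return write_gfa(self.graph, version)


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------


@dataclass
class _Event:
    kind: str  # SNV | INS | DEL | DUP
    pos: int  # SNV: site; INS: anchor (insert after pos); DEL/DUP: span start
    length: int = 1
    alt: str = ""  # SNV alt base or inserted sequence
    carriers: frozenset[str] = frozenset()
    nested: tuple[tuple[int, str, frozenset[str]], ...] = ()  # (offset, alt, carriers)
    source: str | None = None


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


class _Reserver:
    """Interval reservation with a 1 bp guard, for non-overlapping placement."""

    def __init__(self) -> None:
        self.intervals: list[tuple[int, int]] = []

    def free(self, start: int, end: int) -> bool:
        return all(not (start <= e + 1 and end >= s - 1) for s, e in self.intervals)

    def reserve(self, start: int, end: int) -> None:
        self.intervals.append((start, end))


def _place(
    rng: np.random.Generator, reserver: _Reserver, lo: int, hi: int, span: int
) -> int:
    """Draw a start in [lo, hi] such that [start, start+span-1] is free."""
    if hi < lo:
        raise GenerationError("reference too short for requested events")
    for _ in range(1000):
        start = int(rng.integers(lo, hi + 1))
        if reserver.free(start, start + span - 1):
            reserver.reserve(start, start + span - 1)
            return start
    raise GenerationError("could not place event without overlap (retry bound hit)")


def _draw_carriers(
    rng: np.random.Generator, haps: list[str], spec: int | tuple[str, ...] | None
) -> frozenset[str]:
    if isinstance(spec, (tuple, list, set, frozenset)):
        bad = set(spec) - set(haps)
        if bad:
            raise GenerationError(f"unknown carrier haplotypes {sorted(bad)}")
        return frozenset(spec)
    n = spec if isinstance(spec, int) else int(rng.integers(1, len(haps) + 1))
    if not 1 <= n <= len(haps):
        raise GenerationError(f"carrier count {n} out of range")
    idx = rng.choice(len(haps), size=n, replace=False)
    return frozenset(haps[i] for i in sorted(idx))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _plan_events(
    config: SimConfig, rng: np.random.Generator, haps: list[str]
) -> list[_Event]:
    L = config.ref_length
    reserver = _Reserver()
    events: list[_Event] = []
    for spec in config.structural_events:
        carriers = _draw_carriers(rng, haps, spec.carriers)
        if spec.kind in ("INS", "ELEMENT_INS"):
            length = config.element_length if spec.kind == "ELEMENT_INS" else spec.length
            if spec.nested_snvs and len(carriers) < 3:
                raise GenerationError(
                    "an insertion with nested SNVs needs >= 3 carriers so the "
                    "base allele stays the majority"
                )
            pos = _place(rng, reserver, 2, L - 2, 2)
            seq = _rand_seq(rng, length)
            nested: list[tuple[int, str, frozenset[str]]] = []
            if spec.nested_snvs:
                # one minority carrier subset shared by all nested SNVs keeps
                # the unmodified insertion as the majority internal allele
                sub_n = int(rng.integers(1, (len(carriers) - 1) // 2 + 1))
                sub = _draw_carriers(rng, sorted(carriers), sub_n)
                offs = rng.choice(
                    np.arange(2, length), size=spec.nested_snvs, replace=False
                )
                for off in sorted(int(o) for o in offs):
                    nested.append((off, _other_base(rng, seq[off - 1]), sub))
            events.append(
                _Event(
                    kind="INS",
                    pos=pos,
                    length=length,
                    alt=seq,
                    carriers=carriers,
                    nested=tuple(nested),
                    source=spec.kind if spec.kind == "ELEMENT_INS" else None,
                )
            )
        elif spec.kind == "DEL":
            start = _place(rng, reserver, 2, L - spec.length, spec.length)
            events.append(
                _Event(kind="DEL", pos=start, length=spec.length, carriers=carriers)
            )
        elif spec.kind == "DUP":
            start = _place(rng, reserver, 2, L - spec.length, spec.length)
            events.append(
                _Event(
                    kind="DUP",
                    pos=start,
                    length=spec.length,
                    carriers=carriers,
                    source="DUP",
                )
            )
    n_snv = int(rng.binomial(L, config.snv_rate))
    for _ in range(n_snv):
        pos = _place(rng, reserver, 2, L - 1, 1)
        events.append(
            _Event(kind="SNV", pos=pos, carriers=_draw_carriers(rng, haps, None))
        )
    n_indel = int(rng.binomial(L, config.small_indel_rate))
    for _ in range(n_indel):
        length = int(rng.geometric(config.indel_geom_p))
        if rng.random() < 0.5:
            pos = _place(rng, reserver, 2, L - 2, 2)
            events.append(
                _Event(
                    kind="INS",
                    pos=pos,
                    length=length,
                    alt=_rand_seq(rng, length),
                    carriers=_draw_carriers(rng, haps, None),
                )
            )
        else:
            start = _place(rng, reserver, 2, L - length, length)
            events.append(
                _Event(
                    kind="DEL",
                    pos=start,
                    length=length,
                    carriers=_draw_carriers(rng, haps, None),
                )
            )
    return events


def _realize_graph(
    config: SimConfig, ref_seq: str, events: list[_Event], haps: list[str]
) -> tuple[PangenomeGraph, dict[int, dict]]:
    """Build the graph: split the reference at breakpoints, add alt nodes."""
    L = len(ref_seq)
    cuts: set[int] = set()
    for ev in events:
        if ev.kind == "SNV":
            cuts.update({ev.pos - 1, ev.pos})
        elif ev.kind == "INS":
            cuts.add(ev.pos)
        elif ev.kind in ("DEL", "DUP"):
            cuts.update({ev.pos - 1, ev.pos + ev.length - 1})
    cuts.discard(0)
    cuts.discard(L)
    bounds = [0] + sorted(cuts) + [L]
    graph = PangenomeGraph(reference_sample=config.ref_sample)
    seg_counter = 0

    def new_seg(seq: str) -> str:
        nonlocal seg_counter
        seg_counter += 1
        sid = f"s{seg_counter:06d}"
        graph.add_segment(sid, seq)
        return sid

    ref_seg_ids: list[str] = []
    start_to_idx: dict[int, int] = {}
    end_to_idx: dict[int, int] = {}
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        sid = new_seg(ref_seq[a:b])
        ref_seg_ids.append(sid)
        start_to_idx[a + 1] = i  # 1-based start position
        end_to_idx[b] = i  # 1-based end position
    meta: dict[int, dict] = {}
    for k, ev in enumerate(events):
        if ev.kind == "SNV":
            meta[k] = {"alt_seg": new_seg(ev.alt)}
        elif ev.kind == "INS":
            # split the inserted sequence at nested SNV offsets
            icuts: set[int] = set()
            for off, _, _ in ev.nested:
                icuts.update({off - 1, off})
            icuts.discard(0)
            icuts.discard(ev.length)
            ibounds = [0] + sorted(icuts) + [ev.length]
            chain: list[str] = []
            off_to_chain: dict[int, int] = {}
            for ci, (a, b) in enumerate(zip(ibounds, ibounds[1:])):
                chain.append(new_seg(ev.alt[a:b]))
                off_to_chain[a + 1] = ci
            nested_alt = {
                off: new_seg(alt) for off, alt, _ in ev.nested
            }
            meta[k] = {
                "chain": chain,
                "off_to_chain": off_to_chain,
                "nested_alt": nested_alt,
            }
        else:
            meta[k] = {}
    # index events by trigger position
    snv_at = {ev.pos: k for k, ev in enumerate(events) if ev.kind == "SNV"}
    ins_after: dict[int, int] = {
        ev.pos: k for k, ev in enumerate(events) if ev.kind == "INS"
    }
    del_at = {ev.pos: k for k, ev in enumerate(events) if ev.kind == "DEL"}
    dup_end: dict[int, int] = {
        ev.pos + ev.length - 1: k for k, ev in enumerate(events) if ev.kind == "DUP"
    }
    graph.add_path(config.ref_path_name, [(sid, "+") for sid in ref_seg_ids])
    seg_bounds = list(zip(bounds, bounds[1:]))
    for hap in haps:
        steps: list[tuple[str, str]] = []
        i = 0
        while i < len(ref_seg_ids):
            a, b = seg_bounds[i]  # 0-based [a, b)
            start1, end1 = a + 1, b
            k = del_at.get(start1)
            if k is not None and hap in events[k].carriers:
                # skip segments through the end of the deletion span
                dend = events[k].pos + events[k].length - 1
                while seg_bounds[i][1] < dend:
                    i += 1
                i += 1
                continue
            k = snv_at.get(start1)
            if k is not None and hap in events[k].carriers:
                steps.append((meta[k]["alt_seg"], "+"))
            else:
                steps.append((ref_seg_ids[i], "+"))
            k = ins_after.get(end1)
            if k is not None and hap in events[k].carriers:
                m = meta[k]
                for ci, sid in enumerate(m["chain"]):
                    chosen = sid
                    for off, alt_sid in m["nested_alt"].items():
                        if m["off_to_chain"].get(off) == ci and any(
                            hap in sub for o2, _, sub in events[k].nested if o2 == off
                        ):
                            chosen = alt_sid
                    steps.append((chosen, "+"))
            k = dup_end.get(end1)
            if k is not None and hap in events[k].carriers:
                dstart = events[k].pos
                j = start_to_idx[dstart]
                while seg_bounds[j][1] <= end1:
                    steps.append((ref_seg_ids[j], "+"))
                    j += 1
            i += 1
        graph.add_path(hap, steps)
    return graph, meta


def _truth_records(
    config: SimConfig, ref_seq: str, events: list[_Event], haps: list[str]
) -> list[VariantRecord]:
    all_paths = [config.ref_path_name] + haps
    parents: list[tuple[VariantRecord, list[VariantRecord]]] = []
    for ev in events:
        gts: dict[str, int | None] = {
            n: (1 if n in ev.carriers else 0) for n in all_paths
        }
        gts[config.ref_path_name] = 0
        if ev.kind == "SNV":
            rec = VariantRecord(
                contig=config.contig,
                pos=ev.pos,
                ref=ref_seq[ev.pos - 1],
                alts=(ev.alt,),
                kind=SNV,
                genotypes=gts,
            )
            parents.append((rec, []))
        elif ev.kind == "INS":
            anchor = ref_seq[ev.pos - 1]
            pos, ref, alt = ev.pos, anchor, anchor + ev.alt
            children: list[VariantRecord] = []
            if ev.nested:
                for off, alt_base, sub in ev.nested:
                    cgts: dict[str, int | None] = {n: None for n in all_paths}
                    for n in ev.carriers:
                        cgts[n] = 1 if n in sub else 0
                    children.append(
                        VariantRecord(
                            contig=config.contig,
                            pos=off,
                            ref=ev.alt[off - 1],
                            alts=(alt_base,),
                            kind=SNV,
                            genotypes=cgts,
                            parent_pos=pos,
                        )
                    )
            else:
                pos, ref, alt = normalize_variant(pos, ref, alt, ref_seq)
            rec = VariantRecord(
                contig=config.contig,
                pos=pos,
                ref=ref,
                alts=(alt,),
                kind=INS,
                genotypes=gts,
                source=ev.source,
            )
            parents.append((rec, children))
        elif ev.kind == "DEL":
            anchor_pos = ev.pos - 1
            anchor = ref_seq[anchor_pos - 1]
            ref = anchor + ref_seq[ev.pos - 1 : ev.pos - 1 + ev.length]
            pos, ref, alt = normalize_variant(anchor_pos, ref, anchor, ref_seq)
            rec = VariantRecord(
                contig=config.contig,
                pos=pos,
                ref=ref,
                alts=(alt,),
                kind=DEL,
                genotypes=gts,
            )
            parents.append((rec, []))
        elif ev.kind == "DUP":
            # an extra tandem copy is an insertion of the block, left-aligned
            anchor_pos = ev.pos - 1
            anchor = ref_seq[anchor_pos - 1]
            block = ref_seq[ev.pos - 1 : ev.pos - 1 + ev.length]
            pos, ref, alt = normalize_variant(anchor_pos, anchor, anchor + block, ref_seq)
            rec = VariantRecord(
                contig=config.contig,
                pos=pos,
                ref=ref,
                alts=(alt,),
                kind=INS,
                genotypes=gts,
                source="DUP",
            )
            parents.append((rec, []))
    parents.sort(key=lambda rc: (rc[0].contig, rc[0].pos, rc[0].ref, rc[0].alts))
    out: list[VariantRecord] = []
    for idx, (parent, children) in enumerate(parents, start=1):
        parent.id = f"var{idx}"
        parent.parent_pos = None
        out.append(parent)
        for ci, child in enumerate(children, start=1):
            child.id = f"var{idx}.{ci}"
            child.parent = parent.id
            child.parent_pos = parent.pos
            out.append(child)
    return out


def generate_pangenome(config: SimConfig) -> SimResult:
    """Generate a seeded pangenome graph with truth variants and FASTA.

    Identical configs produce byte-identical GFA, FASTA, and VCF output.
    Raises :class:`GenerationError` when events cannot be placed without
    overlap within the retry bound.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref_seq = _rand_seq(rng, config.ref_length)
    haps = config.hap_path_names()
    events = _plan_events(config, rng, haps)
    for ev in events:
        if ev.kind == "SNV" and not ev.alt:
            ev.alt = _other_base(rng, ref_seq[ev.pos - 1])
    graph, _ = _realize_graph(config, ref_seq, events, haps)
    graph.validate()
    truth = TruthSet(
        records=_truth_records(config, ref_seq, events, haps),
        ref_seq=ref_seq,
        contig=config.contig,
        ref_path=config.ref_path_name,
        hap_paths=haps,
    )
    haplotypes = {name: path_sequence(graph, name) for name in graph.paths}
    return SimResult(config=config, graph=graph, truth=truth, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# K locus fixture
# ---------------------------------------------------------------------------

K_GENOTYPES = ("EF/ev21-", "EF/ev21+", "LF/ev21-", "LF/ev21+")


@dataclass
class KLocusFixture:
    """A K-locus-shaped graph with the seven labeled diagnostic edges.

    The locus is entered through e1.  At the element juncture a path either
    skips the insertion via e5 or traverses e6, the element sequence, then
    e7.  At the duplication fork a path either exits via e2 or loops back
    over e3, a short junction segment, and e4 to traverse the duplicated
    block a second time (the late-feathering allele).
    """

    graph: PangenomeGraph
    edges: dict[str, Link]  # e1..e7
    dup_segments: tuple[str, ...]  # the duplicated block
    element_segment: str
    genotypes: dict[str, str]  # sample -> K genotype


def build_k_locus_fixture(
    genotypes: dict[str, str], seed: int = 0, element_length: int = 7_500
) -> KLocusFixture:
    """Build the K-locus graph for the requested per-sample genotypes.

    ``genotypes`` maps sample name to one of ``K_GENOTYPES``.  A reference
    sample "ref" with the EF/ev21- allele is always included (the linear
    reference carries neither the duplication nor the element).
    """
    for sample, gt in genotypes.items():
        if gt not in K_GENOTYPES:
            raise ValueError(f"sample {sample!r}: unknown K genotype {gt!r}")
    rng = np.random.default_rng(seed)
    sizes = {
        "PRE": 2_000,
        "K1": 3_000,
        "EV": element_length,
        "K2A": 1_500,
        "K2B": 1_500,
        "LOOPJ": 30,
        "POST": 2_000,
    }
    graph = PangenomeGraph(reference_sample="ref")
    for sid in ("PRE", "K1", "EV", "K2A", "K2B", "LOOPJ", "POST"):
        graph.add_segment(sid, _rand_seq(rng, sizes[sid]))

    def walk(gt: str) -> list[tuple[str, str]]:
        lf = gt.startswith("LF")
        ev = gt.endswith("ev21+")
        steps = [("PRE", "+"), ("K1", "+")]
        if ev:
            steps.append(("EV", "+"))
        steps += [("K2A", "+"), ("K2B", "+")]
        if lf:
            steps += [("LOOPJ", "+"), ("K2A", "+"), ("K2B", "+")]
        steps.append(("POST", "+"))
        return steps

    graph.add_path("ref#0#chrZ", walk("EF/ev21-"))
    for sample in sorted(genotypes):
        graph.add_path(f"{sample}#1#chrZ", walk(genotypes[sample]))
    edges = {
        "e1": canonical_link("PRE", "+", "K1", "+"),
        "e2": canonical_link("K2B", "+", "POST", "+"),
        "e3": canonical_link("K2B", "+", "LOOPJ", "+"),
        "e4": canonical_link("LOOPJ", "+", "K2A", "+"),
        "e5": canonical_link("K1", "+", "K2A", "+"),
        "e6": canonical_link("K1", "+", "EV", "+"),
        "e7": canonical_link("EV", "+", "K2A", "+"),
    }
    # every labeled edge must exist in the graph when some path uses it; the
    # skip/exit edges always exist via the reference path
    graph.validate()
    return KLocusFixture(
        graph=graph,
        edges=edges,
        dup_segments=("K2A", "K2B"),
        element_segment="EV",
        genotypes=dict(genotypes),
    )
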