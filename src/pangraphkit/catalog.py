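"""Variant cataloging from haplotype paths.

Variants are derived from the graph itself: the ordered segments shared
between the reference path and a haplotype path act as anchors, and every
maximal deviating interval between consecutive anchors is a bubble — the
unit of a variant site.  Where the non-reference alleles of a bubble share
internal anchors among themselves (e.g., SNVs inside an insertion), the
bubble is recursed and the internal variation is reported as nested records
attached to a biallelic parent, rather than exploding the site into one
allele per internal haplotype combination.
"""

from __future__ import annotations

import bisect
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .graph import (
    PangenomeGraph,
    HaplotypePath,
    Step,
    path_sequence,
    reverse_complement,
)

__all__ = [
    "Bubble",
    "VariantRecord",
    "VariantSummary",
    "detect_bubbles",
    "call_variants",
    "summarize_variants",
    "normalize_variant",
    "write_vcf",
    "read_vcf",
]

SNV = "SNV"
INS = "INS"
DEL = "DEL"
COMPLEX = "COMPLEX"

#: indel/SV alleles longer than this are labeled structural
SV_LENGTH_THRESHOLD = 50


@dataclass
class VariantRecord:
    """One bubble-derived variant with per-haplotype calls.

    ``pos`` is the 1-based anchored reference position for top-level records.
    Nested records (``parent`` set) use ``pos`` as the 1-based offset within
    the parent's inserted sequence and carry the parent's reference anchor in
    ``parent_pos``.  ``genotypes`` maps haplotype path name to allele index
    (0 = reference walk) or ``None`` when the haplotype does not traverse
    the site (e.g., non-carriers of the parent insertion at a nested site).
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    kind: str
    genotypes: dict[str, int | None]
    id: str = "."
    parent: str | None = None
    parent_pos: int | None = None
    source: str | None = None
    qual: float | None = None

    @property
    def vcf_pos(self) -> int:
        return self.parent_pos if self.parent_pos is not None else self.pos

    @property
    def called(self) -> int:
        return sum(1 for g in self.genotypes.values() if g is not None)

    @property
    def allele_counts(self) -> list[int]:
        counts = [0] * (len(self.alts) + 1)
        for g in self.genotypes.values():
            if g is not None:
                counts[g] += 1
        return counts

    @property
    def alt_frequency(self) -> float:
        """Fraction of called haplotypes carrying any non-reference allele."""
        called = self.called
        if called == 0:
            return float("nan")
        return sum(1 for g in self.genotypes.values() if g not in (None, 0)) / called

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(h for h, g in self.genotypes.items() if g not in (None, 0))

    @property
    def is_structural(self) -> bool:
        return any(abs(len(a) - len(self.ref)) > SV_LENGTH_THRESHOLD for a in self.alts)

    def key(self) -> tuple:
        """Comparison key for truth matching (ignores record ids)."""
        return (
            self.contig,
            -1 if self.parent_pos is None else self.parent_pos,
            self.pos,
            self.ref,
            self.alts,
        )


def classify_alleles(ref: str, alts: Sequence[str]) -> str:
    kinds = set()
    for alt in alts:
        if len(ref) == 1 and len(alt) == 1:
            kinds.add(SNV)
        elif len(alt) > len(ref) and alt.startswith(ref):
            kinds.add(INS)
        elif len(ref) > len(alt) and ref.startswith(alt):
            kinds.add(DEL)
        else:
            kinds.add(COMPLEX)
    return kinds.pop() if len(kinds) == 1 else COMPLEX


def normalize_variant(
    pos: int, ref: str, alt: str, refseq: str
) -> tuple[int, str, str]:
    """Left-align and trim a biallelic variant against ``refseq`` (1-based pos).

    Standard parsimony/left-alignment: shared trailing bases are trimmed
    (extending to the left over the reference when an allele would empty),
    then shared leading bases are trimmed.  SNVs lose their anchor base;
    indels keep one anchor base on the left.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
                continue
            if pos > 1:
                base = refseq[pos - 2]
                ref, alt = base + ref[:-1], base + alt[:-1]
                pos -= 1
                continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _trim_multiallelic(pos: int, ref: str, alts: list[str]) -> tuple[int, str, list[str]]:
    """Shared prefix/suffix trimming for multiallelic sites (no left shift)."""
    alleles = [ref] + alts
    while all(len(a) > 1 for a in alleles) and len({a[-1] for a in alleles}) == 1:
        alleles = [a[:-1] for a in alleles]
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return pos, alleles[0], alleles[1:]


# ---------------------------------------------------------------------------
# Anchors and bubbles
# ---------------------------------------------------------------------------


def _walk_seq(graph: PangenomeGraph, steps: Iterable[Step]) -> str:
    parts = []
    for s in steps:
        seq = graph.segments[s.segment_id].sequence
        parts.append(seq if s.orient == "+" else reverse_complement(seq))
    return "".join(parts)


def _lis_anchor_indices(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly increasing subsequence of (step_idx, ref_idx) pairs.

    Ties are resolved by the standard patience construction, which for a
    tandem-duplicated block keeps the later copy as anchors, so the extra
    copy surfaces as a left-aligned insertion before the block.
    """
    tails: list[int] = []
    tails_k: list[int] = []
    parent = [-1] * len(pairs)
    for k, (_, ri) in enumerate(pairs):
        p = bisect.bisect_left(tails, ri)
        if p == len(tails):
            tails.append(ri)
            tails_k.append(k)
        else:
            tails[p] = ri
            tails_k[p] = k
        parent[k] = tails_k[p - 1] if p > 0 else -1
    chain = []
    k = tails_k[-1] if tails_k else -1
    while k != -1:
        chain.append(pairs[k])
        k = parent[k]
    return chain[::-1]


def _anchors(
    ref_steps: Sequence[Step], hap_steps: Sequence[Step], ref_index: dict[str, int]
) -> list[tuple[int, int]]:
    """Anchor list [(hap_step_idx, ref_step_idx)] between two walks."""
    pairs = []
    for j, step in enumerate(hap_steps):
        i = ref_index.get(step.segment_id)
        if i is not None and ref_steps[i].orient == step.orient:
            pairs.append((j, i))
    return _lis_anchor_indices(pairs)


def _deviations(
    ref_steps: Sequence[Step],
    hap_steps: Sequence[Step],
    anchors: Sequence[tuple[int, int]],
) -> list[tuple[int, int, tuple[Step, ...]]]:
    """Maximal deviating intervals (ref_i1, ref_i2, hap walk between)."""
    out = []
    for (j1, i1), (j2, i2) in zip(anchors, anchors[1:]):
        hap_between = tuple(hap_steps[j1 + 1 : j2])
        ref_between = tuple(ref_steps[i1 + 1 : i2])
        if hap_between != ref_between:
            out.append((i1, i2, hap_between))
    return out


@dataclass
class Bubble:
    """A variant site: two anchors plus one walk per haplotype between them."""

    contig: str
    ref_path: str
    source_idx: int
    sink_idx: int
    anchor_pos: int  # 1-based ref position of the last base of the source anchor
    ref_walk: tuple[Step, ...]
    source: str = ""  # source anchor segment id
    sink: str = ""  # sink anchor segment id
    walks: dict[str, tuple[Step, ...] | None] = field(default_factory=dict)


def _paths_for_contig(
    graph: PangenomeGraph, ref_path: HaplotypePath, single_ref: bool
) -> list[HaplotypePath]:
    out = []
    for path in graph.paths.values():
        if path.name == ref_path.name:
            continue
        if path.contig == ref_path.contig or single_ref:
            out.append(path)
    return out


def detect_bubbles(
    graph: PangenomeGraph,
) -> tuple[list[Bubble], list[str]]:
    """Find bubbles between the reference path(s) and every haplotype path.

    Returns (bubbles, uncalled) where ``uncalled`` lists haplotype paths that
    share no anchor with their reference path and therefore cannot be
    genotyped.  Bubbles are sorted by reference coordinate.
    """
    ref_paths = graph.reference_paths()
    if not ref_paths:
        raise ValueError("graph has no reference path")
    single_ref = len(ref_paths) == 1
    bubbles: list[Bubble] = []
    uncalled: list[str] = []
    for ref_path in ref_paths:
        ref_steps = ref_path.steps
        ref_index: dict[str, int] = {}
        for i, step in enumerate(ref_steps):
            ref_index.setdefault(step.segment_id, i)
        prefix = [0]
        for step in ref_steps:
            prefix.append(prefix[-1] + len(graph.segments[step.segment_id]))
        haps = _paths_for_contig(graph, ref_path, single_ref)
        hap_anchor_maps: dict[str, dict[int, int]] = {}
        keys: set[tuple[int, int]] = set()
        for hap in haps:
            anchors = _anchors(ref_steps, hap.steps, ref_index)
            if not anchors:
                uncalled.append(hap.name)
                continue
            hap_anchor_maps[hap.name] = {i: j for j, i in anchors}
            for i1, i2, _ in _deviations(ref_steps, hap.steps, anchors):
                keys.add((i1, i2))
        for i1, i2 in sorted(keys):
            bubble = Bubble(
                contig=ref_path.contig,
                ref_path=ref_path.name,
                source_idx=i1,
                sink_idx=i2,
                anchor_pos=prefix[i1 + 1],
                ref_walk=tuple(ref_steps[i1 + 1 : i2]),
                source=ref_steps[i1].segment_id,
                sink=ref_steps[i2].segment_id,
            )
            bubble.walks[ref_path.name] = bubble.ref_walk
            for hap in haps:
                amap = hap_anchor_maps.get(hap.name)
                if amap is None or i1 not in amap or i2 not in amap:
                    bubble.walks[hap.name] = None
                    continue
                j1, j2 = amap[i1], amap[i2]
                if j1 >= j2:
                    bubble.walks[hap.name] = None
                    continue
                bubble.walks[hap.name] = tuple(hap.steps[j1 + 1 : j2])
            bubbles.append(bubble)
    return bubbles, uncalled


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------


def _anchor_base(graph: PangenomeGraph, step: Step) -> str:
    seq = graph.segments[step.segment_id].sequence
    return seq[-1] if step.orient == "+" else reverse_complement(seq)[-1]


def _nest_groups(
    graph: PangenomeGraph,
    groups: list[tuple[tuple[Step, ...], list[str]]],
) -> tuple[tuple[Step, ...], list[str], list[dict], list[tuple[tuple[Step, ...], list[str]]]]:
    """Pick a backbone alt walk and express the other alt walks against it.

    Returns (backbone_walk, backbone+nesting carriers, nested descriptors,
    non-nesting groups).  A descriptor is a dict with within-insertion
    coordinates (pos, ref, alt) and the carrier haplotypes of that internal
    allele.  Groups that share no clean internal anchors with the backbone
    are returned as separate alleles.
    """
    # backbone: most carriers, ties broken by lexicographically smallest seq
    most = max(len(haps) for _, haps in groups)
    backbone, bb_haps = min(
        ((walk, haps) for walk, haps in groups if len(haps) == most),
        key=lambda g: _walk_seq(graph, g[0]),
    )
    bb_haps = list(bb_haps)
    bb_index: dict[str, int] = {}
    for i, step in enumerate(backbone):
        bb_index.setdefault(step.segment_id, i)
    bb_seq = _walk_seq(graph, backbone)
    bb_prefix = [0]
    for step in backbone:
        bb_prefix.append(bb_prefix[-1] + len(graph.segments[step.segment_id]))
    nested: list[dict] = []
    separate: list[tuple[tuple[Step, ...], list[str]]] = []
    carriers = list(bb_haps)
    for walk, haps in groups:
        if walk == backbone:
            continue
        anchors = _anchors(backbone, walk, bb_index)
        devs = _deviations(backbone, walk, anchors) if anchors else []
        clean = (
            bool(anchors)
            and anchors[0] == (0, 0)
            and anchors[-1] == (len(walk) - 1, len(backbone) - 1)
            and devs
        )
        if not clean:
            separate.append((walk, haps))
            continue
        carriers.extend(haps)
        for b1, b2, sub_walk in devs:
            apos = bb_prefix[b1 + 1]  # 1-based offset of anchor base in insertion
            nref = bb_seq[apos - 1] + _walk_seq(graph, tuple(backbone[b1 + 1 : b2]))
            nalt = bb_seq[apos - 1] + _walk_seq(graph, sub_walk)
            npos, nref, nalt = normalize_variant(apos, nref, nalt, bb_seq)
            nested.append({"pos": npos, "ref": nref, "alt": nalt, "haps": list(haps)})
    return backbone, carriers, nested, separate


def call_variants(graph: PangenomeGraph) -> list[VariantRecord]:
    """Derive variant records from every bubble of the graph.

    Each bubble becomes one record, left-anchored with the preceding
    reference base for length-changing alleles and left-aligned against the
    reference sequence.  Haplotypes whose walk matches no enumerated allele
    contribute additional alt alleles (multiallelic records); internal
    variation shared by the alt walks is emitted as nested records carrying
    the parent record id.
    """
    bubbles, _ = detect_bubbles(graph)
    refseqs = {p.name: path_sequence(graph, p.name) for p in graph.reference_paths()}
    all_path_names = list(graph.paths)
    records: list[tuple[VariantRecord, list[VariantRecord]]] = []
    for bubble in bubbles:
        refseq = refseqs[bubble.ref_path]
        anchor = refseq[bubble.anchor_pos - 1]
        ref_allele = anchor + _walk_seq(graph, bubble.ref_walk)
        groups: dict[tuple[Step, ...], list[str]] = {}
        ref_haps: list[str] = []
        missing: list[str] = []
        for name in all_path_names:
            walk = bubble.walks.get(name)
            if walk is None:
                missing.append(name)
            elif walk == bubble.ref_walk:
                ref_haps.append(name)
            else:
                groups.setdefault(walk, []).append(name)
        if not groups:
            continue
        group_list = sorted(
            groups.items(), key=lambda g: _walk_seq(graph, g[0])
        )
        nested_desc: list[dict] = []
        if len(group_list) > 1:
            backbone, ins_carriers, nested_desc, separate = _nest_groups(
                graph, group_list
            )
            alt_walk_sets: list[tuple[str, list[str]]] = [
                (anchor + _walk_seq(graph, backbone), ins_carriers)
            ] + [(anchor + _walk_seq(graph, w), h) for w, h in separate]
        else:
            walk, haps = group_list[0]
            alt_walk_sets = [(anchor + _walk_seq(graph, walk), list(haps))]
        pos = bubble.anchor_pos
        alts = [a for a, _ in alt_walk_sets]
        if nested_desc:
            # nested offsets are defined within the un-shifted insertion
            # allele, so the parent keeps its bubble anchor untouched
            ref_out, alts_out = ref_allele, alts
        elif len(alts) == 1:
            npos, nref, nalt = normalize_variant(pos, ref_allele, alts[0], refseq)
            pos, ref_out, alts_out = npos, nref, [nalt]
        else:
            pos, ref_out, alts_out = _trim_multiallelic(pos, ref_allele, alts)
        genotypes: dict[str, int | None] = {n: None for n in missing}
        for n in ref_haps:
            genotypes[n] = 0
        for ai, (_, haps) in enumerate(alt_walk_sets, start=1):
            for n in haps:
                genotypes[n] = ai
        parent = VariantRecord(
            contig=bubble.contig,
            pos=pos,
            ref=ref_out,
            alts=tuple(alts_out),
            kind=classify_alleles(ref_out, alts_out),
            genotypes=genotypes,
        )
        children: list[VariantRecord] = []
        if nested_desc:
            parent_carriers = {
                n for n, g in genotypes.items() if g == 1
            }
            merged: dict[tuple[int, str, str], list[str]] = {}
            for d in nested_desc:
                merged.setdefault((d["pos"], d["ref"], d["alt"]), []).extend(d["haps"])
            for (npos, nref, nalt), haps in sorted(merged.items()):
                ngt: dict[str, int | None] = {n: None for n in all_path_names}
                for n in parent_carriers:
                    ngt[n] = 0
                for n in haps:
                    ngt[n] = 1
                children.append(
                    VariantRecord(
                        contig=bubble.contig,
                        pos=npos,
                        ref=nref,
                        alts=(nalt,),
                        kind=classify_alleles(nref, (nalt,)),
                        genotypes=ngt,
                        parent_pos=pos,
                    )
                )
        records.append((parent, children))
    records.sort(key=lambda rc: (rc[0].contig, rc[0].pos, rc[0].ref, rc[0].alts))
    out: list[VariantRecord] = []
    for idx, (parent, children) in enumerate(records, start=1):
        parent.id = f"var{idx}"
        out.append(parent)
        for ci, child in enumerate(children, start=1):
            child.id = f"var{idx}.{ci}"
            child.parent = parent.id
            out.append(child)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class VariantSummary:
    counts: dict[str, int]
    cumulative_bp: dict[str, int]
    hist_edges: tuple[int, ...]
    hist_counts: tuple[int, ...]

    def to_tsv(self) -> str:
        lines = ["kind\tcount\tcumulative_bp"]
        for kind in sorted(set(self.counts) | set(self.cumulative_bp)):
            lines.append(
                f"{kind}\t{self.counts.get(kind, 0)}\t{self.cumulative_bp.get(kind, 0)}"
            )
        return "\n".join(lines) + "\n"


def _log_bins(max_len: int) -> tuple[int, ...]:
    edges = [1]
    k = 0
    while edges[-1] <= max_len:
        for m in (2, 5, 10):
            edges.append(m * 10**k)
        k += 1
    return tuple(edges)


def summarize_variants(records: Iterable[VariantRecord]) -> VariantSummary:
    """Counts and cumulative affected bp per kind, plus a length histogram.

    SNVs contribute 1 bp each; indels contribute their length difference.
    The histogram covers |len(alt) - len(ref)| for length-changing alleles,
    with log-spaced (1-2-5 per decade) bins.
    """
    counts: dict[str, int] = {}
    cum: dict[str, int] = {}
    lengths: list[int] = []
    for rec in records:
        counts[rec.kind] = counts.get(rec.kind, 0) + 1
        bp = 0
        for alt in rec.alts:
            d = abs(len(alt) - len(rec.ref))
            if d > 0:
                lengths.append(d)
                bp += d
            else:
                bp += len(alt)
        cum[rec.kind] = cum.get(rec.kind, 0) + bp
    if lengths:
        edges = _log_bins(max(lengths))
        hist, _ = np.histogram(lengths, bins=edges)
        return VariantSummary(counts, cum, edges, tuple(int(h) for h in hist))
    return VariantSummary(counts, cum, (1,), ())


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def write_vcf(
    records: Sequence[VariantRecord],
    sample_names: Sequence[str],
    contig_lengths: dict[str, int] | None = None,
) -> str:
    """Serialize records as VCF 4.2 text with haploid GT columns per sample.

    Nesting is encoded in INFO: ``PARENT`` carries the parent record id and
    ``SUBPOS`` the 1-based offset of a nested record within the parent's
    inserted sequence; nested records are placed at the parent's anchor POS.
    Input must be sorted by (contig, anchored position).
    """
    last: tuple[str, int] | None = None
    for rec in records:
        key = (rec.contig, rec.vcf_pos)
        if last is not None and key < last:
            raise ValueError("records must be sorted by contig and position")
        last = key
    out = io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write("##source=pangraphkit\n")
    for contig, length in sorted((contig_lengths or {}).items()):
        out.write(f"##contig=<ID={contig},length={length}>\n")
    out.write('##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind">\n')
    out.write('##INFO=<ID=PARENT,Number=1,Type=String,Description="Parent record id for nested variants">\n')
    out.write('##INFO=<ID=SUBPOS,Number=1,Type=Integer,Description="1-based offset of a nested variant inside the parent insertion allele">\n')
    out.write('##INFO=<ID=SOURCE,Number=1,Type=String,Description="Simulated event class label">\n')
    out.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Non-reference allele frequency over called haplotypes">\n')
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
        + "\n"
    )
    for rec in records:
        info = [f"KIND={rec.kind}"]
        if rec.parent is not None:
            info.append(f"PARENT={rec.parent}")
            info.append(f"SUBPOS={rec.pos}")
        if rec.source is not None:
            info.append(f"SOURCE={rec.source}")
        af = rec.alt_frequency
        if af == af:  # not NaN
            info.append(f"AF={af:.6g}")
        qual = "." if rec.qual is None else f"{rec.qual:g}"
        gts = []
        for name in sample_names:
            g = rec.genotypes.get(name)
            gts.append("." if g is None else str(g))
        out.write(
            "\t".join(
                [
                    rec.contig,
                    str(rec.vcf_pos),
                    rec.id,
                    rec.ref,
                    ",".join(rec.alts),
                    qual,
                    "PASS",
                    ";".join(info),
                    "GT",
                ]
                + gts
            )
            + "\n"
        )
    return out.getvalue()


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF written by :func:`write_vcf` back into records."""
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for site in vcf:
            info = dict(site.info)
            genotypes: dict[str, int | None] = {}
            for name in samples:
                alleles = site.samples[name]["GT"]
                g = alleles[0] if alleles else None
                genotypes[name] = g
            parent = info.get("PARENT")
            subpos = info.get("SUBPOS")
            records.append(
                VariantRecord(
                    contig=site.contig,
                    pos=int(subpos) if parent is not None else site.pos,
                    ref=site.ref,
                    alts=tuple(site.alts or ()),
                    kind=info.get("KIND", classify_alleles(site.ref, site.alts or ())),
                    genotypes=genotypes,
                    id=site.id or ".",
                    parent=parent,
                    parent_pos=site.pos if parent is not None else None,
                    source=info.get("SOURCE"),
                    qual=site.qual,
                )
            )
    return records, samples
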