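"""Genotype-set comparison between two variant-calling pipelines.

Mirrors the standard intersect-then-compare workflow: variants below a
quality threshold are dropped, records are partitioned into
pipeline-exclusive and shared sets (two records match when they share
contig, position, reference allele, and at least one alternate allele —
"some" semantics), and per-sample / per-variant genotype agreement is
computed over the shared records.  Genotype comparison is on resolved
allele sequences, unordered (0/1 == 1/0), so it survives allele reordering
between files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypedVariant",
    "IntersectionResult",
    "ConcordanceReport",
    "load_vcf_genotypes",
    "intersect_vcfs",
    "per_sample_concordance",
]

SNP = "snp"
INDEL = "indel"


@dataclass
class GenotypedVariant:
    """One VCF record reduced to its comparison-relevant content."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    genotypes: dict[str, tuple[int | None, ...]]  # sample -> allele indices

    @property
    def variant_type(self) -> str:
        return SNP if all(len(a) == 1 for a in (self.ref, *self.alts)) else INDEL

    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.ref)

    def resolved(self, sample: str) -> tuple[str, ...] | None:
        """Genotype as a sorted tuple of allele sequences; None if missing."""
        gt = self.genotypes.get(sample)
        if gt is None or any(a is None for a in gt) or len(gt) == 0:
            return None
        alleles = (self.ref, *self.alts)
        return tuple(sorted(alleles[a] for a in gt))  # type: ignore[index]


def load_vcf_genotypes(path: str | Path) -> tuple[list[GenotypedVariant], list[str]]:
    import pysam

    out: list[GenotypedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for site in vcf:
            genotypes = {}
            for name in samples:
                gt = site.samples[name]["GT"]
                genotypes[name] = tuple(gt) if gt is not None else (None,)
            out.append(
                GenotypedVariant(
                    contig=site.contig,
                    pos=site.pos,
                    ref=(site.ref or "").upper(),
                    alts=tuple((a or "").upper() for a in (site.alts or ())),
                    qual=site.qual,
                    genotypes=genotypes,
                )
            )
    return out, samples


@dataclass
class IntersectionResult:
    a_only: list[GenotypedVariant]
    b_only: list[GenotypedVariant]
    shared: list[tuple[GenotypedVariant, GenotypedVariant]]
    samples: list[str]

    @property
    def n_a(self) -> int:
        return len(self.a_only) + len(self.shared)

    @property
    def n_b(self) -> int:
        return len(self.b_only) + len(self.shared)


def _qual_pass(v: GenotypedVariant, qual_min: float) -> bool:
    return v.qual is None or v.qual >= qual_min


def intersect_vcfs(
    a,
    b,
    qual_min: float = 10.0,
    variant_type: str | None = None,
) -> IntersectionResult:
    """Partition two genotype sets into exclusive and shared records.

    ``a`` and ``b`` are VCF paths or (records, samples) tuples as produced by
    :func:`load_vcf_genotypes`.  Records with QUAL below ``qual_min`` are
    dropped first (records without a QUAL are kept); ``variant_type``
    optionally restricts the comparison to "snp" or "indel" records.  Both
    inputs must carry the same sample columns.
    """
    recs_a, samples_a = a if isinstance(a, tuple) else load_vcf_genotypes(a)
    recs_b, samples_b = b if isinstance(b, tuple) else load_vcf_genotypes(b)
    if list(samples_a) != list(samples_b):
        raise ValueError("the two genotype sets carry different sample columns")

    def keep(recs: Sequence[GenotypedVariant]) -> list[GenotypedVariant]:
        out = [v for v in recs if _qual_pass(v, qual_min)]
        if variant_type is not None:
            out = [v for v in out if v.variant_type == variant_type]
        return out

    recs_a, recs_b = keep(recs_a), keep(recs_b)
    index_b: dict[tuple, list[GenotypedVariant]] = {}
    for v in recs_b:
        index_b.setdefault(v.key(), []).append(v)
    a_only: list[GenotypedVariant] = []
    shared: list[tuple[GenotypedVariant, GenotypedVariant]] = []
    matched_b: set[int] = set()
    for v in recs_a:
        match = None
        for w in index_b.get(v.key(), []):
            if id(w) in matched_b:
                continue
            if set(v.alts) & set(w.alts):
                match = w
                break
        if match is None:
            a_only.append(v)
        else:
            matched_b.add(id(match))
            shared.append((v, match))
    b_only = [w for w in recs_b if id(w) not in matched_b]
    return IntersectionResult(a_only, b_only, shared, list(samples_a))


@dataclass
class ConcordanceReport:
    per_sample: dict[str, float | None]  # percent agreement; None when no data
    per_variant: list[float]  # percent of samples agreeing at each shared site
    mean: float
    sd: float

    def to_tsv(self) -> str:
        lines = ["sample\tconcordance_pct"]
        for name in sorted(self.per_sample):
            v = self.per_sample[name]
            lines.append(f"{name}\t{'NA' if v is None else f'{v:.4f}'}")
        lines.append(f"__mean__\t{self.mean:.4f}")
        lines.append(f"__sd__\t{self.sd:.4f}")
        return "\n".join(lines) + "\n"


def per_sample_concordance(
    result: IntersectionResult, missing_agrees_when_both: bool = True
) -> ConcordanceReport:
    """Genotype agreement over the shared records.

    Agreement at one (site, sample) cell means the unordered multisets of
    resolved allele sequences are identical; a missing genotype against a
    called one is a disagreement, and two missing genotypes agree by default.
    Samples with no shared sites are reported as None and excluded from the
    mean/SD (computed with sample variance, ddof=1).
    """
    if not result.shared:
        raise ValueError("no shared records to compare")
    agree: dict[str, int] = {s: 0 for s in result.samples}
    total: dict[str, int] = {s: 0 for s in result.samples}
    per_variant: list[float] = []
    for va, vb in result.shared:
        n_agree = 0
        for sample in result.samples:
            ga, gb = va.resolved(sample), vb.resolved(sample)
            if ga is None and gb is None:
                ok = missing_agrees_when_both
            elif ga is None or gb is None:
                ok = False
            else:
                ok = ga == gb
            total[sample] += 1
            if ok:
                agree[sample] += 1
                n_agree += 1
        per_variant.append(100.0 * n_agree / len(result.samples))
    per_sample: dict[str, float | None] = {}
    for sample in result.samples:
        per_sample[sample] = (
            100.0 * agree[sample] / total[sample] if total[sample] else None
        )
    values = [v for v in per_sample.values() if v is not None]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return ConcordanceReport(
        per_sample=per_sample, per_variant=per_variant, mean=mean, sd=sd
    )
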