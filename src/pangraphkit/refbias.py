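"""Reference-bias quantification from linear-reference alignments.

Alignment to a single linear reference systematically favors reads carrying
the reference allele at heterozygous sites, depressing the observed
alternate-allele fraction below the expected 0.5.  This module reproduces
the standard pileup-based estimate: filter low-quality and multi-mapping
reads (mapq < 10, secondary/supplementary flags), build per-position base
counts with a depth cap of 100, keep putative heterozygous sites (depth >=
10 and minor-allele fraction >= 25%), and report the deviation of the mean
alternate-allele fraction from 0.5.  Comparing the bias of two alignment
methods yields a percent bias reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PileupSite",
    "HetSite",
    "BiasReport",
    "pileup",
    "is_het_site",
    "find_het_sites",
    "alt_fraction_stats",
    "bias_reduction",
    "simulate_het_sites",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class PileupSite:
    contig: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, int]  # A/C/G/T counts after the depth cap

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class HetSite:
    site: PileupSite
    alt_base: str
    alt_count: int

    @property
    def alt_fraction(self) -> float:
        ref = self.site.counts.get(self.site.ref_base, 0)
        return self.alt_count / (ref + self.alt_count)


@dataclass
class BiasReport:
    n_sites: int
    mean_alt_fraction: float

    @property
    def bias(self) -> float:
        """Magnitude of the deviation from the expected alt fraction 0.5."""
        return abs(self.mean_alt_fraction - 0.5)

    @property
    def signed_bias(self) -> float:
        return self.mean_alt_fraction - 0.5


def pileup(
    sam_path,
    fasta_path,
    min_mapq: int = 10,
    exclude_secondary_supplementary: bool = True,
    depth_cap: int = 100,
) -> list[PileupSite]:
    """Per-position base counts from aligned (match/mismatch) bases.

    Insertions contribute no position; deletions contribute no base.  The
    depth cap is applied in read order: once a position holds ``depth_cap``
    bases, later reads no longer contribute there.  Base qualities are
    ignored.  Raises KeyError when an alignment contig is absent from the
    reference FASTA.
    """
    import pysam
    from pyfaidx import Fasta

    ref = Fasta(str(fasta_path))
    counts: dict[tuple[str, int], dict[str, int]] = {}
    depth: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if exclude_secondary_supplementary and (
                rec.is_secondary or rec.is_supplementary
            ):
                continue
            if rec.mapping_quality < min_mapq:
                continue
            contig = rec.reference_name
            if contig not in ref:
                raise KeyError(f"contig {contig!r} absent from reference FASTA")
            seq = rec.query_sequence or ""
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in _BASES:
                    continue
                key = (contig, rpos)
                if depth.get(key, 0) >= depth_cap:
                    continue
                depth[key] = depth.get(key, 0) + 1
                counts.setdefault(key, {})[base] = counts.get(key, {}).get(base, 0) + 1
    sites = []
    for (contig, rpos) in sorted(counts):
        ref_base = str(ref[contig][rpos]).upper()
        sites.append(
            PileupSite(
                contig=contig,
                pos=rpos + 1,
                ref_base=ref_base,
                counts=counts[(contig, rpos)],
            )
        )
    return sites


def is_het_site(
    counts: dict[str, int], min_depth: int = 10, min_minor_frac: float = 0.25
) -> bool:
    """The putative-heterozygous-site filter as a pure function of counts.

    A site qualifies iff its (capped) depth is at least ``min_depth`` and the
    second-most-frequent base — the minor allele, which may or may not be the
    reference — accounts for at least ``min_minor_frac`` of the depth.
    """
    depth = sum(counts.values())
    if depth < min_depth:
        return False
    top_two = sorted(counts.values(), reverse=True)[:2]
    if len(top_two) < 2:
        return False
    return top_two[1] / depth >= min_minor_frac


def find_het_sites(
    sites: Iterable[PileupSite],
    min_depth: int = 10,
    min_minor_frac: float = 0.25,
) -> list[HetSite]:
    """Filter pileup sites to putative heterozygous sites.

    The alternate allele is the most frequent non-reference base (ties broken
    in A<C<G<T order); the minor allele used by the filter is the
    second-most-frequent base overall.
    """
    out = []
    for site in sites:
        if not is_het_site(site.counts, min_depth, min_minor_frac):
            continue
        non_ref = [
            (site.counts.get(b, 0), b) for b in _BASES if b != site.ref_base
        ]
        alt_count, alt_base = max(non_ref, key=lambda t: (t[0], -_BASES.index(t[1])))
        if alt_count == 0:
            continue
        out.append(HetSite(site=site, alt_base=alt_base, alt_count=alt_count))
    return out


def alt_fraction_stats(het_sites: Sequence[HetSite]) -> BiasReport:
    """Mean alternate-allele fraction over het sites and its bias from 0.5."""
    if not het_sites:
        raise ValueError("no heterozygous sites")
    fracs = [h.alt_fraction for h in het_sites]
    return BiasReport(n_sites=len(fracs), mean_alt_fraction=float(np.mean(fracs)))


def bias_reduction(bias_linear: float, bias_graph: float) -> float:
    """Percent reduction of reference bias between two alignment methods."""
    if bias_linear <= 0:
        raise ValueError("bias reduction undefined for non-positive linear bias")
    return 100.0 * (bias_linear - bias_graph) / bias_linear


def simulate_het_sites(
    n_sites: int,
    depth: int,
    alt_prob: float,
    rng: np.random.Generator,
    contig: str = "chr1",
) -> list[HetSite]:
    """Binomially sampled het-site read counts with a given alt probability.

    A lightweight stand-in for a full alignment round-trip: each site draws
    alt reads ~ Binomial(depth, alt_prob) with 'A' as reference and 'G' as
    alternate.  Sites failing the het filter are kept anyway (the caller is
    sampling at a known het site), matching a genotype-aware analysis.
    """
    alt_counts = rng.binomial(depth, alt_prob, size=n_sites)
    out = []
    for i, k in enumerate(alt_counts):
        k = int(k)
        site = PileupSite(
            contig=contig, pos=i + 1, ref_base="A", counts={"A": depth - k, "G": k}
        )
        out.append(HetSite(site=site, alt_base="G", alt_count=k))
    return out
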