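"""Greedy attribution of accessory graph sequence to samples.

Starting from a chosen base assembly, all segments traversed by any of the
base sample's haplotype paths are removed; then, iteratively, the remaining
sample whose haplotype paths traverse the largest total length of remaining
segments is recorded and its segments removed, until no samples remain.
Segments traversed by no path at all are reported as residual.  The base
traversed length, the recorded contributions, and the residual always sum
exactly to the total graph length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import PangenomeGraph

__all__ = ["AttributionResult", "attribute_accessory"]


@dataclass
class AttributionResult:
    base_sample: str
    base_bp: int  # total length of segments traversed by the base sample
    contributions: list[tuple[str, int]]  # greedy order
    residual_bp: int  # segments traversed by no path
    total_bp: int  # total graph sequence

    def to_tsv(self) -> str:
        lines = ["rank\tsample\tbp"]
        lines.append(f"0\t{self.base_sample}\t{self.base_bp}")
        for rank, (sample, bp) in enumerate(self.contributions, start=1):
            lines.append(f"{rank}\t{sample}\t{bp}")
        lines.append(f".\t__residual__\t{self.residual_bp}")
        return "\n".join(lines) + "\n"


def attribute_accessory(graph: PangenomeGraph, base_sample: str) -> AttributionResult:
    """Iterative greedy accessory-sequence attribution.

    At each step the contribution of a sample is the summed length of
    still-unremoved segments traversed by any path whose PanSN sample field
    matches; the maximum is taken, ties broken lexicographically by sample
    name.  Raises KeyError for an unknown base sample.
    """
    sample_segments: dict[str, set[str]] = {}
    for path in graph.paths.values():
        sample_segments.setdefault(path.sample, set()).update(
            s.segment_id for s in path.steps
        )
    if base_sample not in sample_segments:
        raise KeyError(f"unknown base sample {base_sample!r}")
    seg_len = {sid: len(seg) for sid, seg in graph.segments.items()}
    total_bp = sum(seg_len.values())
    removed = set(sample_segments[base_sample])
    base_bp = sum(seg_len[s] for s in removed)
    remaining = sorted(s for s in sample_segments if s != base_sample)
    contributions: list[tuple[str, int]] = []
    while remaining:
        sums = {
            s: sum(seg_len[sid] for sid in sample_segments[s] - removed)
            for s in remaining
        }
        best_sum = max(sums.values())
        best = min(s for s in remaining if sums[s] == best_sum)
        contributions.append((best, sums[best]))
        removed |= sample_segments[best]
        remaining.remove(best)
    covered = set().union(*sample_segments.values()) if sample_segments else set()
    residual_bp = sum(l for sid, l in seg_len.items() if sid not in covered)
    return AttributionResult(
        base_sample=base_sample,
        base_bp=base_bp,
        contributions=contributions,
        residual_bp=residual_bp,
        total_bp=total_bp,
    )
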