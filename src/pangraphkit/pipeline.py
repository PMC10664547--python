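"""End-to-end demonstration pipeline on generated data.

Runs the full analysis sequence — simulate a pangenome, catalog its
variants against the truth set, attribute accessory sequence, simulate
reads, score alignment accuracy, genotype the K-locus events from reads,
quantify reference bias, and compare genotype sets — writing per-stage
outputs plus a machine-readable report and checksum manifest.  The whole
run is deterministic under its seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import (
    ErrorModel,
    SimConfig,
    SVEventSpec,
    alt_fraction_stats,
    attribute_accessory,
    bias_reduction,
    call_variants,
    evaluate_alignments,
    generate_pangenome,
    graph_stats,
    intersect_vcfs,
    per_sample_concordance,
    simulate_reads,
    summarize_variants,
    truth_graph_alignments,
    write_vcf,
)
from .concordance import load_vcf_genotypes
from .graph import path_sequence
from .reads import gaf_to_aligned, truth_to_reference
from .refbias import simulate_het_sites
from .simulate import build_k_locus_fixture, K_GENOTYPES
from .sv import count_edge_support, genotype_sv, k_locus_event_models, node_path_coverage

logger = logging.getLogger("pangraphkit")

__all__ = ["RunConfig", "run_demo"]


@dataclass
class RunConfig:
    seed: int = 42
    out_dir: str = "demo_out"
    sim: SimConfig | None = None
    error_model: ErrorModel = field(default_factory=ErrorModel)
    n_read_pairs: int = 2000
    read_len: int = 150
    qual_min: float = 10.0
    alpha: float = 0.05
    het_sites: int = 2000
    het_depth: int = 30

    def resolved_sim(self) -> SimConfig:
        if self.sim is not None:
            return self.sim
        return SimConfig(
            seed=self.seed,
            ref_length=30_000,
            n_haplotypes=8,
            snv_rate=1e-3,
            small_indel_rate=2e-4,
            structural_events=(
                SVEventSpec("INS", 300, carriers=4, nested_snvs=2),
                SVEventSpec("DEL", 1_000),
                SVEventSpec("DUP", 400),
                SVEventSpec("ELEMENT_INS", carriers=2),
            ),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, t0: float) -> float:
    t1 = time.time()
    logger.info("stage %-16s done in %.2fs", name, t1 - t0)
    return t1


def run_demo(config: RunConfig) -> dict:
    """Execute every stage on generated data; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    t0 = time.time()

    # --- simulate pangenome -------------------------------------------------
    sim = generate_pangenome(config.resolved_sim())
    (out / "graph.gfa").write_text(sim.gfa("1.1"))
    (out / "haplotypes.fa").write_text(sim.fasta())
    (out / "truth.vcf").write_text(sim.truth.to_vcf())
    report["stages"]["simulate"] = {
        "n_truth_variants": len(sim.truth.records),
        "n_haplotypes": len(sim.truth.hap_paths) + 1,
    }
    t0 = _stage("simulate", t0)

    # --- graph statistics ---------------------------------------------------
    stats = graph_stats(sim.graph)
    (out / "graph_stats.tsv").write_text(stats.summary_tsv())
    report["stages"]["stats"] = {
        "n_segments": stats.n_segments,
        "n_links": stats.n_links,
        "mean_degree": round(stats.mean_degree, 1),
        "total_length": stats.total_length,
    }
    t0 = _stage("stats", t0)

    # --- variant catalog ----------------------------------------------------
    records = call_variants(sim.graph)
    samples = [sim.truth.ref_path] + sim.truth.hap_paths
    (out / "called.vcf").write_text(
        write_vcf(records, samples, {sim.truth.contig: len(sim.truth.ref_seq)})
    )
    summary = summarize_variants(records)
    (out / "variant_summary.tsv").write_text(summary.to_tsv())
    truth_keys = {(r.key(), r.carriers) for r in sim.truth.records}
    called_keys = {(r.key(), r.carriers) for r in records}
    recovery = (
        len(truth_keys & called_keys) / len(truth_keys) if truth_keys else 1.0
    )
    edit_ok = all(
        sim.haplotypes[n] == sim.truth.reconstruct(n) for n in sim.truth.hap_paths
    )
    report["stages"]["catalog"] = {
        "n_called": len(records),
        "truth_recovery": recovery,
        "editing_oracle_ok": edit_ok,
    }
    t0 = _stage("catalog", t0)

    # --- accessory attribution ----------------------------------------------
    attribution = attribute_accessory(sim.graph, sim.graph.reference_sample)
    (out / "accessory.tsv").write_text(attribution.to_tsv())
    conserved = (
        attribution.base_bp
        + sum(bp for _, bp in attribution.contributions)
        + attribution.residual_bp
        == attribution.total_bp
    )
    report["stages"]["accessory"] = {
        "base_bp": attribution.base_bp,
        "conservation_ok": conserved,
    }
    t0 = _stage("accessory", t0)

    # --- read simulation + accuracy curve -----------------------------------
    read_set = simulate_reads(
        sim.graph,
        path_names=sim.truth.hap_paths[:1],
        n_pairs=config.n_read_pairs,
        read_len=config.read_len,
        error_model=config.error_model,
        seed=config.seed + 1,
    )
    fq1, fq2 = read_set.fastq()
    (out / "reads_1.fastq").write_text(fq1)
    (out / "reads_2.fastq").write_text(fq2)
    (out / "reads_truth.tsv").write_text(read_set.truth_tsv())
    gaf = truth_graph_alignments(sim.graph, read_set)
    curve = evaluate_alignments(
        truth_to_reference(sim.graph, read_set), gaf_to_aligned(gaf, sim.graph)
    )
    (out / "accuracy_curve.tsv").write_text(curve.to_tsv())
    report["stages"]["reads"] = {
        "n_pairs": config.n_read_pairs,
        "sub_rate": read_set.total_subs / read_set.total_bases,
        "indel_event_rate": read_set.total_indel_events / read_set.total_bases,
        "accuracy_at_0": curve.at(0),
        "accuracy_at_60": curve.at(60),
    }
    t0 = _stage("reads", t0)

    # --- K-locus genotyping -------------------------------------------------
    k_samples = {f"bird{i}": gt for i, gt in enumerate(K_GENOTYPES, start=1)}
    fixture = build_k_locus_fixture(k_samples, seed=config.seed + 2)
    events = k_locus_event_models(fixture.edges, alpha=config.alpha)
    cov = node_path_coverage(fixture.graph)
    k_rows = ["sample\tgenotype\tevent\tk_presence\tk_absence\tcall"]
    n_correct = 0
    for i, (sample, gt) in enumerate(sorted(k_samples.items())):
        path = f"{sample}#1#chrZ"
        plen = len(path_sequence(fixture.graph, path))
        n_pairs = plen * 30 // (2 * config.read_len)
        k_reads = simulate_reads(
            fixture.graph,
            [path],
            n_pairs=n_pairs,
            read_len=config.read_len,
            error_model=config.error_model,
            seed=config.seed + 10 + i,
        )
        alns = truth_graph_alignments(fixture.graph, k_reads)
        support = count_edge_support(alns, events, fixture.graph)
        expected = {
            "ev21_insertion": "present" if gt.endswith("ev21+") else "absent",
            "tandem_duplication": "present" if gt.startswith("LF") else "absent",
        }
        for model in events:
            call = genotype_sv(support[model.name], model, sample=sample)
            k_rows.append(
                f"{sample}\t{gt}\t{model.name}\t{call.k_presence}\t"
                f"{call.k_absence}\t{call.call}"
            )
            if call.call == expected[model.name]:
                n_correct += 1
    (out / "k_locus_calls.tsv").write_text("\n".join(k_rows) + "\n")
    lf_cov_ok = all(
        cov.get(sid, f"{s}#1#chrZ") == 2
        for sid in fixture.dup_segments
        for s, gt in k_samples.items()
        if gt.startswith("LF")
    )
    report["stages"]["k_locus"] = {
        "n_calls": 2 * len(k_samples),
        "n_correct": n_correct,
        "lf_double_coverage_ok": lf_cov_ok,
    }
    t0 = _stage("k_locus", t0)

    # --- reference bias -----------------------------------------------------
    rng = np.random.default_rng(config.seed + 3)
    linear_sites = simulate_het_sites(config.het_sites, config.het_depth, 0.46, rng)
    graph_sites = simulate_het_sites(config.het_sites, config.het_depth, 0.50, rng)
    bias_lin = alt_fraction_stats(linear_sites)
    bias_gra = alt_fraction_stats(graph_sites)
    reduction = bias_reduction(bias_lin.bias, bias_gra.bias)
    (out / "refbias.tsv").write_text(
        "method\tn_sites\tmean_alt_fraction\tbias\n"
        f"linear\t{bias_lin.n_sites}\t{bias_lin.mean_alt_fraction:.4f}\t{bias_lin.bias:.4f}\n"
        f"graph\t{bias_gra.n_sites}\t{bias_gra.mean_alt_fraction:.4f}\t{bias_gra.bias:.4f}\n"
        f"reduction_pct\t.\t.\t{reduction:.1f}\n"
    )
    report["stages"]["refbias"] = {
        "bias_linear": bias_lin.bias,
        "bias_graph": bias_gra.bias,
        "reduction_pct": reduction,
    }
    t0 = _stage("refbias", t0)

    # --- concordance --------------------------------------------------------
    inter = intersect_vcfs(
        load_vcf_genotypes(out / "truth.vcf"),
        load_vcf_genotypes(out / "called.vcf"),
        qual_min=config.qual_min,
    )
    conc = per_sample_concordance(inter)
    (out / "concordance.tsv").write_text(conc.to_tsv())
    report["stages"]["concordance"] = {
        "shared": len(inter.shared),
        "a_only": len(inter.a_only),
        "b_only": len(inter.b_only),
        "mean_pct": conc.mean,
    }
    t0 = _stage("concordance", t0)

    # --- manifest -----------------------------------------------------------
    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix != ".json"
    }
    report["manifest"] = manifest
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
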