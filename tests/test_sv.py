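"""Path coverage, duplication runs, edge support, binomial SV genotyping."""

import math
from collections import Counter
from functools import lru_cache

import numpy as np
import pytest

from pangraphkit import (
    GraphAlignment,
    PangenomeGraph,
    SimConfig,
    SVEventModel,
    canonical_link,
    count_edge_support,
    detect_duplications,
    generate_pangenome,
    genotype_sv,
    k_locus_event_models,
    node_path_coverage,
    simulate_reads,
    truth_graph_alignments,
)
from pangraphkit.graph import Step, path_sequence
from pangraphkit.sv import EdgeSupport, load_event_models, dump_event_models


# -- exact two-sided binomial p-value, independent of scipy ------------------


@lru_cache(maxsize=None)
def exact_two_sided_pvalue(k: int, n: int, p: float) -> float:
    pmf = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    cutoff = pmf[k] * (1 + 1e-9)
    return min(1.0, sum(q for q in pmf if q <= cutoff))


def oracle_call(kp, ka, theta_p, theta_a, alpha=0.05, min_reads=4):
    n = kp + ka
    if n < min_reads:
        return "no_data"
    pp = exact_two_sided_pvalue(kp, n, theta_p)
    pa = exact_two_sided_pvalue(kp, n, theta_a)
    if pp > alpha and pa <= alpha:
        return "present"
    if pa > alpha and pp <= alpha:
        return "absent"
    return "inconclusive"


class TestPathCoverage:
    def test_linear_chain_all_ones(self, toy_chain):
        cov = node_path_coverage(toy_chain)
        assert all(
            cov.get(sid, "ref#0#chr1") == 1 for sid in toy_chain.segments
        )

    def test_k_fixture_lf_counts_two_on_duplicated_block(self, k_fixture):
        cov = node_path_coverage(k_fixture.graph)
        for sid in k_fixture.dup_segments:
            assert cov.get(sid, "dual#1#chrZ") == 2
            assert cov.get(sid, "early#1#chrZ") == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_equal_brute_force_step_tally(self, seed):
        res = generate_pangenome(
            SimConfig(seed=seed, ref_length=3000, n_haplotypes=5, snv_rate=3e-3,
                      small_indel_rate=1e-3)
        )
        cov = node_path_coverage(res.graph)
        brute = Counter()
        for name, path in res.graph.paths.items():
            for step in path.steps:
                brute[(step.segment_id, name)] += 1
        assert cov.counts == dict(brute)

    def test_coverage_times_length_equals_path_length(self, k_fixture):
        cov = node_path_coverage(k_fixture.graph)
        for name in k_fixture.graph.paths:
            assert cov.path_total_bp(k_fixture.graph, name) == len(
                path_sequence(k_fixture.graph, name)
            )


class TestDuplicationRuns:
    def test_no_duplication_gives_empty_list(self, toy_chain):
        runs = detect_duplications(node_path_coverage(toy_chain), toy_chain)
        assert runs == []

    def test_k_fixture_one_run_per_lf_haplotype(self, k_fixture):
        runs = detect_duplications(node_path_coverage(k_fixture.graph), k_fixture.graph)
        lf_paths = {
            f"{s}#1#chrZ"
            for s, gt in k_fixture.genotypes.items()
            if gt.startswith("LF")
        }
        assert {r.path for r in runs} == lf_paths
        for r in runs:
            assert r.segments == k_fixture.dup_segments
            assert r.max_count == 2

    def test_two_disjoint_duplications_stay_separate(self):
        g = PangenomeGraph(reference_sample="ref")
        for sid in "abcde":
            g.add_segment(sid, "ACGTACGT")
        g.add_path("ref#0#c", [(s, "+") for s in "abcde"])
        g.add_path(
            "s#1#c",
            [("a", "+"), ("a", "+"), ("b", "+"), ("c", "+"),
             ("d", "+"), ("d", "+"), ("e", "+")],
        )
        runs = detect_duplications(node_path_coverage(g), g)
        mine = [r for r in runs if r.path == "s#1#c"]
        assert [r.segments for r in mine] == [("a",), ("d",)]


class TestEdgeSupport:
    def _graph(self):
        g = PangenomeGraph()
        g.add_segment("a", "ACGTA")  # 5 bp
        g.add_segment("b", "GGTTC")  # 5 bp
        g.add_path("p", [("a", "+"), ("b", "+")])
        return g

    def _event(self):
        return SVEventModel(
            name="x",
            presence_edges=(canonical_link("a", "+", "b", "+"),),
            absence_edges=(canonical_link("b", "+", "a", "+"),),
        )

    def test_read_spanning_junction_supports_edge(self):
        g, ev = self._graph(), self._event()
        aln = GraphAlignment("r", (Step("a", "+"), Step("b", "+")), 3, 8)
        support = count_edge_support([aln], [ev], g)["x"]
        assert support.k_presence == 1

    def test_read_ending_exactly_at_junction_does_not_support(self):
        g, ev = self._graph(), self._event()
        ending = GraphAlignment("r1", (Step("a", "+"), Step("b", "+")), 0, 5)
        starting = GraphAlignment("r2", (Step("a", "+"), Step("b", "+")), 5, 10)
        support = count_edge_support([ending, starting], [ev], g)["x"]
        assert support.k_presence == 0

    def test_reverse_orientation_walk_supports_same_edge(self):
        g, ev = self._graph(), self._event()
        aln = GraphAlignment("r", (Step("b", "-"), Step("a", "-")), 2, 9)
        assert count_edge_support([aln], [ev], g)["x"].k_presence == 1

    def test_unknown_segment_skips_read_with_tally(self):
        g, ev = self._graph(), self._event()
        bad = GraphAlignment("r", (Step("zz", "+"), Step("b", "+")), 0, 6)
        support = count_edge_support([bad], [ev], g)["x"]
        assert support.n_skipped == 1 and support.k_presence == 0

    def test_simulated_coverage_proportional_support(self, k_fixture):
        path = "evonly#1#chrZ"
        plen = len(path_sequence(k_fixture.graph, path))
        n_pairs = plen * 30 // 300
        rs = simulate_reads(k_fixture.graph, [path], n_pairs=n_pairs, seed=8)
        events = k_locus_event_models(k_fixture.edges)
        support = count_edge_support(
            truth_graph_alignments(k_fixture.graph, rs), events, k_fixture.graph
        )
        ins = support["ev21_insertion"]
        # ~30x coverage over a 150 bp-spannable junction => dozens of reads
        assert ins.k_presence > 10
        assert ins.k_absence == 0


class TestGenotyper:
    INSERTION = dict(theta_p=0.98, theta_a=0.02)

    def _model(self, theta_p=0.98, theta_a=0.02, min_reads=4):
        return SVEventModel(
            name="ev",
            presence_edges=(canonical_link("a", "+", "b", "+"),),
            absence_edges=(canonical_link("a", "+", "c", "+"),),
            theta_present=theta_p,
            theta_absent=theta_a,
            min_reads=min_reads,
        )

    def _call(self, kp, ka, **kwargs):
        model = self._model(**kwargs)
        return genotype_sv(EdgeSupport("ev", kp, ka), model).call

    def test_clear_present_and_absent(self):
        assert self._call(30, 0) == "present"
        assert self._call(0, 30) == "absent"

    def test_below_min_reads_is_no_data(self):
        assert self._call(1, 1) == "no_data"
        assert self._call(3, 0) == "no_data"
        assert self._call(1, 1, min_reads=2) == "inconclusive"

    def test_small_n_grid_matches_exact_binomial_oracle(self):
        model = self._model(min_reads=2)
        for n in range(0, 7):
            for kp in range(n + 1):
                ka = n - kp
                got = genotype_sv(EdgeSupport("ev", kp, ka), model).call
                want = oracle_call(kp, ka, 0.98, 0.02, min_reads=2)
                assert got == want, (kp, ka)

    def test_monotonicity_over_exhaustive_grid(self):
        """More presence reads never flip a present call to absent."""
        model = self._model()
        for ka in range(0, 41):
            seen_present = False
            for kp in range(0, 41 - ka):
                call = genotype_sv(EdgeSupport("ev", kp, ka), model).call
                if call == "present":
                    seen_present = True
                if seen_present:
                    assert call != "absent", (kp, ka)

    def test_recovery_over_500_simulated_events(self):
        """Conclusive calls match the simulated genotype; zero swaps."""
        rng = np.random.default_rng(42)
        ins_model = self._model(theta_p=0.98)
        dup_model = self._model(theta_p=0.5)
        n_reads = 30
        results = []
        for i in range(500):
            model = ins_model if i % 2 == 0 else dup_model
            truth = "present" if (i // 2) % 2 == 0 else "absent"
            theta = model.theta_present if truth == "present" else model.theta_absent
            kp = int(rng.binomial(n_reads, theta))
            call = genotype_sv(EdgeSupport("ev", kp, n_reads - kp), model).call
            results.append((truth, call))
        swaps = sum(
            1 for truth, call in results
            if call in ("present", "absent") and call != truth
        )
        conclusive = [r for r in results if r[1] in ("present", "absent")]
        assert swaps == 0
        assert len(conclusive) / len(results) > 0.95
        correct = sum(1 for truth, call in conclusive if truth == call)
        assert correct / len(conclusive) >= 0.99

    def test_all_low_coverage_events_return_no_data(self):
        for kp in range(3):
            for ka in range(3 - kp):
                assert self._call(kp, ka) == "no_data"

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            self._model(theta_p=0.02, theta_a=0.98)


class TestKLocusGenotyping:
    def test_all_four_genotype_combinations_called_independently(self, k_fixture):
        events = k_locus_event_models(k_fixture.edges)
        for i, (sample, gt) in enumerate(sorted(k_fixture.genotypes.items())):
            path = f"{sample}#1#chrZ"
            plen = len(path_sequence(k_fixture.graph, path))
            rs = simulate_reads(
                k_fixture.graph, [path], n_pairs=plen * 30 // 300, seed=100 + i
            )
            support = count_edge_support(
                truth_graph_alignments(k_fixture.graph, rs), events, k_fixture.graph
            )
            expected = {
                "ev21_insertion": "present" if gt.endswith("+") else "absent",
                "tandem_duplication": "present" if gt.startswith("LF") else "absent",
            }
            for model in events:
                call = genotype_sv(support[model.name], model, sample=sample)
                assert call.call == expected[model.name], (sample, model.name)

    def test_lf_loop_support_is_roughly_one_to_one(self, k_fixture):
        """A hemizygous LF walk feeds loop-back and exit edges ~1:1."""
        path = "lfonly#1#chrZ"
        plen = len(path_sequence(k_fixture.graph, path))
        rs = simulate_reads(k_fixture.graph, [path], n_pairs=plen * 40 // 300, seed=5)
        events = k_locus_event_models(k_fixture.edges)
        support = count_edge_support(
            truth_graph_alignments(k_fixture.graph, rs), events, k_fixture.graph
        )["tandem_duplication"]
        ratio = support.k_presence / (support.k_presence + support.k_absence)
        assert 0.3 < ratio < 0.7


def test_event_model_round_trip(tmp_path, k_fixture):
    events = k_locus_event_models(k_fixture.edges)
    path = tmp_path / "events.json"
    path.write_text(dump_event_models(events))
    assert load_event_models(path) == events
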