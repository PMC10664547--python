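"""Graph model, GFA/GAF I/O, path sequences, statistics, projection."""

import io

import pytest

from pangraphkit import (
    GraphAlignment,
    PangenomeGraph,
    SimConfig,
    canonical_link,
    generate_pangenome,
    graph_stats,
    mean_degree,
    parse_gaf,
    parse_gfa,
    path_sequence,
    project_to_reference,
    reverse_complement,
    write_gaf,
    write_gfa,
)
from pangraphkit.graph import (
    GFAParseError,
    GraphValidationError,
    parse_pansn,
    path_interval_walk,
)

from conftest import parse_gfa_text


class TestGFAParsing:
    def test_counts_from_minimal_gfa(self):
        text = (
            "H\tVN:Z:1.0\n"
            "S\ta\tACGT\nS\tb\tT\nS\tc\tGG\n"
            "L\ta\t+\tb\t+\t0M\nL\tb\t+\tc\t+\t0M\n"
            "P\tref#0#chr1\ta+,b+,c+\t*\n"
        )
        g = parse_gfa_text(text)
        assert (len(g.segments), len(g.links), len(g.paths)) == (3, 2, 1)

    def test_w_line_builds_pansn_name(self):
        text = "S\tx\tAC\nS\ty\tGT\nL\tx\t+\ty\t+\t0M\nW\ts1\t1\tchr1\t0\t4\t>x>y\n"
        g = parse_gfa_text(text)
        assert list(g.paths) == ["s1#1#chr1"]
        path = g.paths["s1#1#chr1"]
        assert (path.sample, path.haplotype, path.contig) == ("s1", "1", "chr1")

    def test_unknown_segment_in_path_is_validation_error(self):
        text = "S\ta\tAC\nP\tp\ta+,zz+\t*\n"
        with pytest.raises(GraphValidationError, match="zz"):
            parse_gfa_text(text)

    @pytest.mark.parametrize(
        "bad",
        ["S\tonlyid\n", "L\ta\t+\tb\t+\t5M\n", "P\tname\n", "W\ts\t1\tc\t0\t4\n"],
    )
    def test_malformed_line_reports_line_number(self, bad):
        with pytest.raises(GFAParseError, match="line 1"):
            parse_gfa_text(bad)

    def test_write_is_deterministic_and_version_1_1_round_trips(self, toy_chain):
        for version in ("1.0", "1.1"):
            text = write_gfa(toy_chain, version)
            assert text == write_gfa(toy_chain, version)
            assert parse_gfa_text(text, "ref") == toy_chain
        assert any(line.startswith("W\tref\t0\tchr1") for line in write_gfa(toy_chain, "1.1").splitlines())

    def test_empty_path_graph_writes_only_header_and_segments(self):
        g = PangenomeGraph()
        g.add_segment("a", "ACGT")
        tags = {line.split("\t")[0] for line in write_gfa(g).splitlines()}
        assert tags == {"H", "S"}

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip_identity_on_random_graphs(self, seed):
        cfg = SimConfig(
            seed=seed,
            ref_length=400,
            n_haplotypes=3,
            snv_rate=5e-3,
            small_indel_rate=2e-3,
        )
        g = generate_pangenome(cfg).graph
        for version in ("1.0", "1.1"):
            assert parse_gfa_text(write_gfa(g, version)) == g


class TestPanSN:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("s1#1#chr1", ("s1", "1", "chr1")),
            ("chrZ", ("chrZ", "0", "chrZ")),
            ("bird#chr2", ("bird", "0", "chr2")),
        ],
    )
    def test_parse(self, name, expected):
        assert parse_pansn(name) == expected


class TestPathSequence:
    def test_concatenation(self):
        g = PangenomeGraph()
        g.add_segment("A", "ACG")
        g.add_segment("B", "T")
        g.add_segment("C", "GG")
        g.add_path("p", [("A", "+"), ("B", "+"), ("C", "+")])
        assert path_sequence(g, "p") == "ACGTGG"

    def test_minus_step_contributes_reverse_complement(self):
        g = PangenomeGraph()
        g.add_segment("B", "AAC")
        g.add_path("p", [("B", "-")])
        assert path_sequence(g, "p") == "GTT"
        assert reverse_complement("AAC") == "GTT"

    def test_duplicated_block_gives_a_plus_2b_plus_c_length(self):
        g = PangenomeGraph()
        g.add_segment("A", "ACGTACGTAC")
        g.add_segment("B", "TTTTT")
        g.add_segment("C", "GGGGGGG")
        g.add_path("dup", [("A", "+"), ("B", "+"), ("B", "+"), ("C", "+")])
        assert len(path_sequence(g, "dup")) == 10 + 2 * 5 + 7
        # the graph itself holds only A + B + C
        stats = graph_stats(g)
        assert stats.total_length == 10 + 5 + 7
        assert stats.path_length["dup"] == 27

    def test_unknown_path_raises(self, toy_chain):
        with pytest.raises(KeyError):
            path_sequence(toy_chain, "nope")


class TestGraphStats:
    @pytest.mark.parametrize(
        "links,segments", [(67_000_000, 49_000_000), (45_000_000, 33_000_000)]
    )
    def test_published_pangenome_counts_give_mean_degree_1_4(self, links, segments):
        assert round(mean_degree(links, segments), 1) == 1.4

    def test_chain_lengths_all_agree(self, toy_chain):
        stats = graph_stats(toy_chain)
        assert stats.total_length == 22
        assert stats.path_length["ref#0#chr1"] == 22
        assert stats.traversed_length["ref"] == 22

    def test_path_length_counts_repeats_but_traversed_does_not(self):
        g = PangenomeGraph()
        g.add_segment("A", "ACGT")
        g.add_segment("B", "GG")
        g.add_path("s#1#c", [("A", "+"), ("B", "+"), ("B", "+")])
        stats = graph_stats(g)
        assert stats.path_length["s#1#c"] == 8
        assert stats.traversed_length["s"] == 6
        assert stats.path_length["s#1#c"] > stats.traversed_length["s"]

    def test_total_length_is_path_independent(self, toy_chain):
        before = graph_stats(toy_chain).total_length
        toy_chain.paths.clear()
        g2 = PangenomeGraph(
            segments=toy_chain.segments, links=toy_chain.links, paths={}
        )
        assert graph_stats(g2).total_length == before

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            graph_stats(PangenomeGraph())


class TestProjection:
    def test_on_reference_positions(self, toy_chain):
        coord = project_to_reference(toy_chain, "B", 2)
        assert (coord.contig, coord.position, coord.on_reference) == ("chr1", 13, True)
        first = project_to_reference(toy_chain, "A", 0)
        assert (first.position, first.on_reference) == (1, True)

    def test_insertion_node_anchors_to_preceding_reference_base(self):
        g = PangenomeGraph(reference_sample="ref")
        g.add_segment("A", "ACGTACGTAC")  # ref pos 1..10
        g.add_segment("I", "TTT")  # insertion between 10 and 11
        g.add_segment("B", "GGGGG")  # ref pos 11..15
        g.add_path("ref#0#chr1", [("A", "+"), ("B", "+")])
        g.add_path("s#1#chr1", [("A", "+"), ("I", "+"), ("B", "+")])
        coord = project_to_reference(g, "I", 1)
        assert (coord.position, coord.on_reference) == (10, False)

    def test_unreachable_segment_errors(self, toy_chain):
        toy_chain.add_segment("island", "AC")
        with pytest.raises(ValueError, match="unreachable"):
            project_to_reference(toy_chain, "island", 0)

    def test_offset_bounds_checked(self, toy_chain):
        with pytest.raises(ValueError):
            project_to_reference(toy_chain, "B", 5)


class TestGAF:
    def test_round_trip(self, toy_chain):
        aln = GraphAlignment(
            "r1/1", toy_chain.paths["ref#0#chr1"].steps, 3, 15, mapq=42
        )
        text = write_gaf([aln], toy_chain)
        back = parse_gaf(io.StringIO(text))
        assert back == [aln]

    def test_interval_walk_offsets(self, toy_chain):
        walk, ws, we = path_interval_walk(toy_chain, "ref#0#chr1", 8, 17)
        assert [s.segment_id for s in walk] == ["A", "B", "C"]
        assert (ws, we) == (8, 17)
        walk, ws, we = path_interval_walk(toy_chain, "ref#0#chr1", 10, 15)
        assert [s.segment_id for s in walk] == ["B"]
        assert (ws, we) == (0, 5)


def test_canonical_link_identifies_reverse_traversal():
    assert canonical_link("a", "+", "b", "+") == canonical_link("b", "-", "a", "-")
    g = PangenomeGraph()
    g.add_segment("a", "A")
    g.add_segment("b", "C")
    g.add_link("a", "+", "b", "+")
    g.add_link("b", "-", "a", "-")
    assert len(g.links) == 1
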