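"""Bubble detection, variant calling, truth recovery, summaries, VCF I/O."""

import pytest

from pangraphkit import (
    PangenomeGraph,
    SimConfig,
    SVEventSpec,
    VariantRecord,
    call_variants,
    detect_bubbles,
    generate_pangenome,
    normalize_variant,
    read_vcf,
    summarize_variants,
    write_vcf,
)


class TestBubbles:
    def test_snv_site_gives_one_bubble_with_two_alleles(self, snv_site_graph):
        bubbles, uncalled = detect_bubbles(snv_site_graph)
        assert uncalled == []
        assert len(bubbles) == 1
        walks = {tuple(s.segment_id for s in w) for w in bubbles[0].walks.values()}
        assert walks == {("refb",), ("altb",)}

    def test_deletion_haplotype_has_empty_allele_walk(self):
        g = PangenomeGraph(reference_sample="ref")
        g.add_segment("a", "ACGTACGTAC")
        g.add_segment("d", "G" * 100)  # stands in for the deleted block
        g.add_segment("b", "TTGACCAGTA")
        g.add_path("ref#0#c", [("a", "+"), ("d", "+"), ("b", "+")])
        for i in range(1, 30):
            steps = (
                [("a", "+"), ("b", "+")] if i == 1
                else [("a", "+"), ("d", "+"), ("b", "+")]
            )
            g.add_path(f"S{i:02d}#1#c", steps)
        bubbles, _ = detect_bubbles(g)
        assert len(bubbles) == 1
        assert bubbles[0].walks["S01#1#c"] == ()
        assert len(bubbles[0].walks["S02#1#c"]) == 1

    def test_haplotype_sharing_no_anchor_is_reported_uncalled(self, toy_chain):
        toy_chain.add_segment("x", "TTTT")
        toy_chain.add_segment("y", "GGGG")
        toy_chain.add_path("lost#1#chr1", [("x", "+"), ("y", "+")])
        bubbles, uncalled = detect_bubbles(toy_chain)
        assert uncalled == ["lost#1#chr1"]


class TestCallVariants:
    def test_igll1_style_snv_frequency_is_17_percent(self, snv_site_graph):
        records = call_variants(snv_site_graph)
        assert len(records) == 1
        rec = records[0]
        assert rec.kind == "SNV"
        assert (rec.ref, rec.alts) == ("G", ("A",))
        assert len(rec.carriers) == 5 and rec.called == 30
        assert round(100 * rec.alt_frequency) == 17

    def test_rare_deletion_frequency(self):
        g = PangenomeGraph(reference_sample="ref")
        g.add_segment("a", "ACGTACGTAC")
        g.add_segment("d", "G" * 50)
        g.add_segment("b", "TTGACCAGTA")
        g.add_path("ref#0#c", [("a", "+"), ("d", "+"), ("b", "+")])
        for i in range(1, 30):
            steps = (
                [("a", "+"), ("b", "+")] if i == 1
                else [("a", "+"), ("d", "+"), ("b", "+")]
            )
            g.add_path(f"S{i:02d}#1#c", steps)
        records = call_variants(g)
        assert len(records) == 1
        assert records[0].kind == "DEL"
        assert records[0].alt_frequency == pytest.approx(1 / 30)

    def test_insertion_with_internal_snv_stays_biallelic_with_nested_record(self):
        g = PangenomeGraph(reference_sample="ref")
        g.add_segment("a", "ACGTACGTAC")
        g.add_segment("b", "TTGACCAGTA")
        g.add_segment("i1", "CCC")
        g.add_segment("m", "A")
        g.add_segment("mv", "T")
        g.add_segment("i2", "GGG")
        g.add_path("ref#0#c", [("a", "+"), ("b", "+")])
        ins = [("a", "+"), ("i1", "+"), ("m", "+"), ("i2", "+"), ("b", "+")]
        ins_var = [("a", "+"), ("i1", "+"), ("mv", "+"), ("i2", "+"), ("b", "+")]
        plain = [("a", "+"), ("b", "+")]
        for i, steps in enumerate([ins, ins, ins_var, plain, plain], start=1):
            g.add_path(f"S{i}#1#c", steps)
        records = call_variants(g)
        parents = [r for r in records if r.parent is None]
        children = [r for r in records if r.parent is not None]
        assert len(parents) == 1 and len(children) == 1
        parent, child = parents[0], children[0]
        assert parent.kind == "INS" and len(parent.alts) == 1
        assert parent.alts[0] == "C" + "CCCAGGG"
        assert parent.carriers == {"S1#1#c", "S2#1#c", "S3#1#c"}
        assert child.kind == "SNV"
        assert (child.pos, child.ref, child.alts) == (4, "A", ("T",))
        assert child.carriers == {"S3#1#c"}
        assert child.genotypes["S4#1#c"] is None  # no insertion, no site

    @pytest.mark.parametrize("seed", range(10))
    def test_truth_recovery_on_generated_graphs(self, seed):
        cfg = SimConfig(
            seed=seed, ref_length=10_000, n_haplotypes=8, snv_rate=2e-3,
            small_indel_rate=5e-4,
            structural_events=(
                SVEventSpec("INS", 250, carriers=4, nested_snvs=2),
                SVEventSpec("DEL", 400),
                SVEventSpec("DUP", 150),
            ),
        )
        res = generate_pangenome(cfg)
        records = call_variants(res.graph)
        truth = {(r.key(), r.carriers) for r in res.truth.records}
        called = {(r.key(), r.carriers) for r in records}
        assert called == truth
        # genotype-exact, not only carrier-exact
        truth_gt = {
            (r.key(), tuple(sorted(r.genotypes.items())))
            for r in res.truth.records
        }
        called_gt = {
            (r.key(), tuple(sorted(r.genotypes.items()))) for r in records
        }
        assert called_gt == truth_gt

    def test_biallelic_frequencies_sum_to_one(self, mixed_sim):
        for rec in call_variants(mixed_sim.graph):
            if len(rec.alts) == 1:
                counts = rec.allele_counts
                assert counts[0] + counts[1] == rec.called
                ref_freq = counts[0] / rec.called
                assert ref_freq + rec.alt_frequency == pytest.approx(1.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (5, "AG", "AT", (6, "G", "T")),  # anchored SNV loses its anchor
            (5, "A", "AGG", (5, "A", "AGG")),  # already minimal insertion
            (4, "TAAA", "T", (4, "TAAA", "T")),  # deletion already anchored
        ],
    )
    def test_trim(self, pos, ref, alt, expected):
        refseq = "CCCTAAAGGG"
        assert normalize_variant(pos, ref, alt, refseq) == expected

    def test_left_shift_through_homopolymer(self):
        refseq = "CCAAAATGG"  # deleting any single A is the same variant
        pos, ref, alt = normalize_variant(6, "AA", "A", refseq)
        assert (pos, ref, alt) == (2, "CA", "C")


class TestSummaries:
    def test_empty_is_all_zeros(self):
        summary = summarize_variants([])
        assert summary.counts == {} and summary.cumulative_bp == {}

    def test_cumulative_lengths(self):
        gts = {"h": 1}
        ins = VariantRecord("c", 10, "A", ("A" + "G" * 300,), "INS", dict(gts))
        dele = VariantRecord("c", 500, "A" + "T" * 5000, ("A",), "DEL", dict(gts))
        snv = VariantRecord("c", 9000, "G", ("C",), "SNV", dict(gts))
        summary = summarize_variants([ins, dele, snv])
        assert summary.cumulative_bp == {"INS": 300, "DEL": 5000, "SNV": 1}
        assert summary.counts == {"INS": 1, "DEL": 1, "SNV": 1}
        assert sum(summary.hist_counts) == 2  # indel lengths only

    def test_summary_matches_truth_totals(self, mixed_sim):
        records = call_variants(mixed_sim.graph)
        summary = summarize_variants(records)
        expected: dict[str, int] = {}
        for rec in mixed_sim.truth.records:
            for alt in rec.alts:
                d = abs(len(alt) - len(rec.ref))
                expected[rec.kind] = expected.get(rec.kind, 0) + (d if d else len(alt))
        assert summary.cumulative_bp == expected


class TestVCF:
    def test_single_snv_record_layout(self, snv_site_graph):
        records = call_variants(snv_site_graph)
        samples = sorted(snv_site_graph.paths)
        text = write_vcf(records, samples)
        data = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(data) == 1
        fields = data[0].split("\t")
        assert fields[3] == "G" and fields[4] == "A" and fields[8] == "GT"

    def test_insertion_ref_is_single_anchor_base(self, mixed_sim):
        records = call_variants(mixed_sim.graph)
        samples = [mixed_sim.truth.ref_path] + mixed_sim.truth.hap_paths
        for line in write_vcf(records, samples).splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            if "KIND=INS" in f[7]:
                assert len(f[3]) == 1

    def test_write_read_round_trip(self, tmp_path, mixed_sim):
        records = call_variants(mixed_sim.graph)
        samples = [mixed_sim.truth.ref_path] + mixed_sim.truth.hap_paths
        vcf = tmp_path / "out.vcf"
        vcf.write_text(
            write_vcf(records, samples,
                      {mixed_sim.truth.contig: len(mixed_sim.truth.ref_seq)})
        )
        back, back_samples = read_vcf(vcf)
        assert back_samples == samples
        assert [(r.key(), r.carriers) for r in back] == [
            (r.key(), r.carriers) for r in records
        ]

    def test_unsorted_input_rejected(self):
        gts = {"h": 1}
        a = VariantRecord("c", 100, "A", ("T",), "SNV", dict(gts))
        b = VariantRecord("c", 50, "G", ("C",), "SNV", dict(gts))
        with pytest.raises(ValueError, match="sorted"):
            write_vcf([a, b], ["h"])
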