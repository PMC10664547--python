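import io

import pytest

from pangraphkit import PangenomeGraph, SVEventSpec, SimConfig, generate_pangenome
from pangraphkit.simulate import build_k_locus_fixture


@pytest.fixture
def toy_chain():
    """A(10bp), B(5bp), C(7bp) chain with one reference path covering all."""
    g = PangenomeGraph(reference_sample="ref")
    g.add_segment("A", "ACGTACGTAC")
    g.add_segment("B", "ACGTA")
    g.add_segment("C", "ACGTACG")
    g.add_path("ref#0#chr1", [("A", "+"), ("B", "+"), ("C", "+")])
    g.validate()
    return g


def make_snv_site_graph(n_haplotypes: int = 30, n_carriers: int = 5):
    """A single SNV bubble: shared flanks, ref base vs alt base.

    The reference plus (n_haplotypes - 1) alternate haplotypes; n_carriers
    of the alternates take the alt node.
    """
    g = PangenomeGraph(reference_sample="ref")
    g.add_segment("pre", "ACGTACGTAA")
    g.add_segment("refb", "G")
    g.add_segment("altb", "A")
    g.add_segment("post", "TTGACCAGTA")
    g.add_path("ref#0#chr15", [("pre", "+"), ("refb", "+"), ("post", "+")])
    for i in range(1, n_haplotypes):
        mid = "altb" if i <= n_carriers else "refb"
        g.add_path(f"S{i:02d}#1#chr15", [("pre", "+"), (mid, "+"), ("post", "+")])
    g.validate()
    return g


@pytest.fixture
def snv_site_graph():
    return make_snv_site_graph()


@pytest.fixture
def mixed_sim():
    """A mid-sized generated pangenome with every event class."""
    cfg = SimConfig(
        seed=11,
        ref_length=20_000,
        n_haplotypes=8,
        snv_rate=1e-3,
        small_indel_rate=3e-4,
        structural_events=(
            SVEventSpec("INS", 300, carriers=4, nested_snvs=2),
            SVEventSpec("DEL", 800),
            SVEventSpec("DUP", 250),
            SVEventSpec("ELEMENT_INS", carriers=2),
        ),
    )
    return generate_pangenome(cfg)


@pytest.fixture
def k_fixture():
    return build_k_locus_fixture(
        {
            "dual": "LF/ev21+",
            "early": "EF/ev21-",
            "lfonly": "LF/ev21-",
            "evonly": "EF/ev21+",
        },
        seed=3,
    )


def parse_gfa_text(text: str, reference_sample: str = ""):
    from pangraphkit import parse_gfa

    return parse_gfa(io.StringIO(text), reference_sample=reference_sample)
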