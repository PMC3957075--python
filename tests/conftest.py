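"""Shared fixtures: a hand-written toy ontology and the worked example."""

import textwrap

import pytest

from ftc import classify, generate_random_kb, make_figure1_fixture, parse_obo
from ftc.synthetic import FixtureSpec

# 12-term GO-like toy: a coagulation branch with signed regulation terms,
# one MF term, one obsolete term.  The expected adjacency is written out
# by hand in tests that consume it.
TOY_OBO = textwrap.dedent("""\
    format-version: 1.2
    ontology: toy-go

    [Term]
    id: GO:0008150
    name: biological process root
    namespace: biological_process

    [Term]
    id: GO:0050817
    name: coagulation
    namespace: biological_process
    is_a: GO:0008150

    [Term]
    id: GO:0007596
    name: blood coagulation
    namespace: biological_process
    is_a: GO:0050817

    [Term]
    id: GO:0042730
    name: fibrinolysis
    namespace: biological_process
    is_a: GO:0050817
    relationship: part_of GO:0007596

    [Term]
    id: GO:0030193
    name: regulation of blood coagulation
    namespace: biological_process
    relationship: regulates GO:0007596

    [Term]
    id: GO:0030194
    name: positive regulation of blood coagulation
    namespace: biological_process
    is_a: GO:0030193
    relationship: positively_regulates GO:0007596

    [Term]
    id: GO:0030195
    name: negative regulation of blood coagulation
    namespace: biological_process
    is_a: GO:0030193
    relationship: negatively_regulates GO:0007596

    [Term]
    id: GO:0043084
    name: penile erection
    namespace: biological_process
    is_a: GO:0008150

    [Term]
    id: GO:0060407
    name: negative regulation of penile erection
    namespace: biological_process
    relationship: negatively_regulates GO:0043084

    [Term]
    id: GO:0003674
    name: molecular function root
    namespace: molecular_function

    [Term]
    id: GO:0008900
    name: hydrogen:potassium-exchanging ATPase activity
    namespace: molecular_function
    is_a: GO:0003674

    [Term]
    id: GO:0000099
    name: withdrawn process
    namespace: biological_process
    is_obsolete: true
    """)

#: Non-obsolete toy terms without a regulates-family out-edge.
TOY_NON_REGULATION_TERMS = (
    "GO:0008150",
    "GO:0050817",
    "GO:0007596",
    "GO:0042730",
    "GO:0043084",
    "GO:0003674",
    "GO:0008900",
)


@pytest.fixture(scope="session")
def toy_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toy.obo"
    path.write_text(TOY_OBO, encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def toy_graph(toy_obo_path):
    return parse_obo(str(toy_obo_path))


@pytest.fixture(scope="session")
def fig1():
    return make_figure1_fixture()


@pytest.fixture(scope="session")
def fig1_build(fig1):
    return classify(fig1.kb)


def random_fixture(seed, **overrides):
    """Small seeded knowledge base used across property tests."""
    params = dict(
        seed=seed,
        n_terms=30,
        n_drugs=8,
        n_proteins=10,
        regulation_fraction=0.3,
        links_per_drug=2,
    )
    params.update(overrides)
    return generate_random_kb(FixtureSpec(**params))
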