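import dataclasses

import pytest

from ftc import (
    Polarity,
    ancestor_closure,
    brute_force_oracle,
    category_id,
    classify,
    map_action_to_sign,
    polypharmacology_stats,
)
from ftc.ontology_io import Drug, KnowledgeBase, PerturbationLink, ProteinAnnotation

from conftest import random_fixture


@pytest.mark.parametrize(
    "action,expected",
    [
        ("inhibitor", -1),
        ("antagonist", -1),
        ("blocker", -1),
        ("AGONIST", +1),
        ("Activator", +1),
        ("binder", "unknown"),
        ("", "unknown"),
    ],
)
def test_map_action_to_sign(action, expected):
    assert map_action_to_sign(action) == expected


def test_map_action_custom_table():
    assert map_action_to_sign("ligand", {"ligand": +1}) == +1
    assert map_action_to_sign("inhibitor", {"ligand": +1}) == "unknown"


def test_worked_example_single_direct_membership(fig1, fig1_build):
    """An inhibitor of an activator of coagulation is an anti-coagulant."""
    direct = [m for m in fig1_build.memberships if m.kind == "direct"]
    assert len(direct) == 1
    m = direct[0]
    assert m.drug_id == "DB04898"
    assert m.category_id == "FTC_A0007596"
    assert fig1_build.memberships_by_drug("direct") == {
        d: set(v) for d, v in fig1.ground_truth.direct.items()
    }
    # complete provenance chain: link, annotation, regulation step
    (chain,) = m.provenance
    for piece in ("DB04898", "inhibitor", "P00734", "GO:0030194", "reg+1", "GO:0007596"):
        assert piece in chain


def test_worked_example_sign_flip(fig1):
    """Swapping the inhibitor for an agonist flips the polarity to Pro-."""
    kb = fig1.kb
    flipped = KnowledgeBase(
        kb.graph,
        kb.annotations,
        kb.drugs,
        [dataclasses.replace(kb.links[0], action_term="agonist", sign=+1)],
    )
    build = classify(flipped)
    direct = [m for m in build.memberships if m.kind == "direct"]
    assert [(m.drug_id, m.category_id) for m in direct] == [("DB04898", "FTC_P0007596")]


def test_double_negative_yields_pro(toy_graph):
    """Inhibiting a negative regulator of X promotes X (-1 * -1 = PRO)."""
    kb = KnowledgeBase(
        toy_graph,
        [ProteinAnnotation("P1", "GO:0030195")],  # negative regulation of coagulation
        [Drug("DB1")],
        [PerturbationLink("DB1", "P1", "inhibitor", -1)],
    )
    direct = classify(kb).memberships_by_drug("direct")
    assert direct["DB1"] == {category_id("GO:0007596", Polarity.PRO)}


def test_direct_annotation_branch(toy_graph):
    """An agonist of a protein annotated straight to X lands in Pro-X."""
    kb = KnowledgeBase(
        toy_graph,
        [ProteinAnnotation("P1", "GO:0042730")],
        [Drug("DB1")],
        [PerturbationLink("DB1", "P1", "agonist", +1)],
    )
    direct = classify(kb).memberships_by_drug("direct")
    assert direct["DB1"] == {category_id("GO:0042730", Polarity.PRO)}


def test_unknown_action_is_inert(toy_graph):
    kb = KnowledgeBase(
        toy_graph,
        [ProteinAnnotation("P1", "GO:0042730")],
        [Drug("DB1")],
        [PerturbationLink("DB1", "P1", "binder", "unknown")],
    )
    assert classify(kb).memberships == []


def test_neutral_regulation_is_inert(toy_graph):
    kb = KnowledgeBase(
        toy_graph,
        [ProteinAnnotation("P1", "GO:0030193")],  # neutral 'regulation of'
        [Drug("DB1")],
        [PerturbationLink("DB1", "P1", "inhibitor", -1)],
    )
    assert classify(kb).memberships == []


def test_empty_drug_list_full_taxonomy(toy_graph):
    build = classify(KnowledgeBase(toy_graph, [], [], []))
    assert build.memberships == []
    assert build.metrics["n_categories"] == 14


def test_ancestor_closure_idempotent_and_disjoint():
    for seed in range(10):
        build = classify(random_fixture(seed).kb)
        direct = [m for m in build.memberships if m.kind == "direct"]
        indirect = ancestor_closure(direct, build.taxonomy)
        again = ancestor_closure(direct + indirect, build.taxonomy)
        as_pairs = lambda ms: {(m.drug_id, m.category_id) for m in ms}
        # the closed set is a fixed point: re-closing adds nothing new
        assert as_pairs(again) == set()
        # direct and indirect never overlap per drug
        assert not as_pairs(direct) & as_pairs(indirect)
        # direct + indirect is closed under taxonomy ancestors
        union = as_pairs(direct) | as_pairs(indirect)
        for drug, cid in union:
            for anc in build.taxonomy.ancestors(cid):
                assert (drug, anc) in union


def test_closure_of_root_only_membership(fig1_build):
    from ftc.classifier import MembershipAssignment

    root = fig1_build.taxonomy.roots[0]
    direct = [MembershipAssignment("DBX", root, "direct")]
    assert ancestor_closure(direct, fig1_build.taxonomy) == []


def _flip_links(kb):
    flipped = [
        dataclasses.replace(l, sign=-l.sign) if l.sign != "unknown" else l
        for l in kb.links
    ]
    return KnowledgeBase(kb.graph, kb.annotations, kb.drugs, flipped)


def _flip_cid(cid):
    code = {"FTC_P": "FTC_A", "FTC_A": "FTC_P"}[cid[:5]]
    return code + cid[5:]


def test_sign_antisymmetry():
    """Flipping every perturbation sign flips every direct membership."""
    for seed in range(10):
        kb = random_fixture(seed).kb
        direct = {
            (m.drug_id, m.category_id)
            for m in classify(kb).memberships
            if m.kind == "direct"
        }
        flipped = {
            (m.drug_id, m.category_id)
            for m in classify(_flip_links(kb)).memberships
            if m.kind == "direct"
        }
        assert flipped == {(d, _flip_cid(c)) for d, c in direct}


def _dc_pairs(build):
    # membership identity is (drug, category); kind may upgrade
    return {(m.drug_id, m.category_id) for m in build.memberships}


def test_monotonicity_adding_a_link():
    """Adding a link never removes a (drug, category) membership."""
    for seed in range(5):
        kb = random_fixture(seed).kb
        before = _dc_pairs(classify(kb))
        protein = kb.annotations[0].protein_id
        extra = PerturbationLink(kb.drugs[0].drug_id, protein, "inhibitor", -1)
        bigger = KnowledgeBase(kb.graph, kb.annotations, kb.drugs, kb.links + [extra])
        assert _dc_pairs(classify(bigger)) >= before


def test_monotonicity_adding_an_annotation():
    for seed in range(5):
        kb = random_fixture(seed).kb
        before = _dc_pairs(classify(kb))
        linked_protein = kb.links[0].protein_id
        term = next(t for t in kb.graph.terms if not kb.graph.terms[t].obsolete)
        extra = ProteinAnnotation(linked_protein, term)
        bigger = KnowledgeBase(kb.graph, kb.annotations + [extra], kb.drugs, kb.links)
        assert _dc_pairs(classify(bigger)) >= before


def test_oracle_equivalence_sample():
    for seed in range(20):
        kb = random_fixture(seed, n_terms=35, n_drugs=10).kb
        assert classify(kb).membership_pairs() == brute_force_oracle(kb).membership_pairs()


def test_determinism_and_input_order_invariance():
    kb = random_fixture(3).kb
    reference = classify(kb).memberships
    assert classify(kb).memberships == reference
    reshuffled = KnowledgeBase(
        kb.graph,
        list(reversed(kb.annotations)),
        list(reversed(kb.drugs)),
        list(reversed(kb.links)),
    )
    assert {
        (m.drug_id, m.category_id, m.kind, m.provenance)
        for m in classify(reshuffled).memberships
    } == {(m.drug_id, m.category_id, m.kind, m.provenance) for m in reference}


def test_polypharmacology_counts(fig1_build):
    stats = polypharmacology_stats(fig1_build)
    (row,) = stats["per_drug"]
    assert row == {"drug_id": "DB04898", "direct": 1, "total": 2}
    assert stats["direct"]["mean"] == 1.0
    assert stats["total"]["range"] == 0


def test_polypharmacology_matches_oracle_recount():
    synth = random_fixture(11, n_clusters=2)
    build = classify(synth.kb)
    stats = polypharmacology_stats(build)
    oracle = brute_force_oracle(synth.kb)
    odirect = oracle.memberships_by_drug("direct")
    ototal = oracle.memberships_by_drug(None)
    for row in stats["per_drug"]:
        assert row["direct"] == len(odirect.get(row["drug_id"], ()))
        assert row["total"] == len(ototal.get(row["drug_id"], ()))
    classified = [r for r in stats["per_drug"] if r["total"]]
    assert stats["direct"]["mean"] == pytest.approx(
        sum(r["direct"] for r in classified) / len(classified)
    )
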