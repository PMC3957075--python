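import random

import pytest

from ftc import classify, generate_categories, parse_atc, parse_drug_targets, parse_gaf, parse_obo
from ftc.ontology_io import (
    KnowledgeBase,
    OntologyValidationError,
    ParseError,
    parse_evaluation_points,
    write_outputs,
)

from conftest import TOY_NON_REGULATION_TERMS


def test_parse_obo_minimal_dag(tmp_path):
    obo = tmp_path / "mini.obo"
    obo.write_text(
        "format-version: 1.2\n\n[Term]\nid: X:0000001\nname: x\n"
        "is_a: Y:0000001\n\n[Term]\nid: Y:0000001\nname: y\n"
    )
    graph = parse_obo(str(obo))
    assert len(graph.terms) == 2
    assert [(e.child, e.parent, e.relation) for e in graph.edges] == [
        ("X:0000001", "Y:0000001", "is_a")
    ]


def test_parse_obo_toy_adjacency(toy_graph):
    """The 12-term toy parses to the hand-written adjacency list."""
    assert len(toy_graph.terms) == 12
    edges = {(e.child, e.parent, e.relation) for e in toy_graph.edges}
    assert edges == {
        ("GO:0050817", "GO:0008150", "is_a"),
        ("GO:0007596", "GO:0050817", "is_a"),
        ("GO:0042730", "GO:0050817", "is_a"),
        ("GO:0042730", "GO:0007596", "part_of"),
        ("GO:0030193", "GO:0007596", "regulates"),
        ("GO:0030194", "GO:0030193", "is_a"),
        ("GO:0030194", "GO:0007596", "positively_regulates"),
        ("GO:0030195", "GO:0030193", "is_a"),
        ("GO:0030195", "GO:0007596", "negatively_regulates"),
        ("GO:0043084", "GO:0008150", "is_a"),
        ("GO:0060407", "GO:0043084", "negatively_regulates"),
        ("GO:0008900", "GO:0003674", "is_a"),
    }
    assert toy_graph.terms["GO:0008900"].namespace == "molecular_function"


def test_obsolete_term_recorded_but_inert(toy_graph):
    assert toy_graph.terms["GO:0000099"].obsolete
    assert all(
        "GO:0000099" not in (e.child, e.parent) for e in toy_graph.edges
    )
    categories = generate_categories(toy_graph)
    assert all(c.anchor_term != "GO:0000099" for c in categories.values())


def test_unsupported_relation_dropped(tmp_path):
    obo = tmp_path / "rel.obo"
    obo.write_text(
        "format-version: 1.2\n\n[Term]\nid: X:0000001\nname: x\n"
        "relationship: has_part Y:0000001\n\n[Term]\nid: Y:0000001\nname: y\n"
    )
    graph = parse_obo(str(obo))
    assert graph.edges == []


def test_cycle_raises(tmp_path):
    obo = tmp_path / "cycle.obo"
    obo.write_text(
        "format-version: 1.2\n\n[Term]\nid: X:0000001\nname: x\nis_a: Y:0000001\n\n"
        "[Term]\nid: Y:0000001\nname: y\nis_a: X:0000001\n"
    )
    with pytest.raises(OntologyValidationError, match="cycle"):
        parse_obo(str(obo))


GAF_HEADER = "!gaf-version: 2.1\n"


def _gaf_row(protein, term, qualifier="", evidence="IDA"):
    fields = [
        "UniProtKB", protein, protein, qualifier, term, "PMID:0", evidence,
        "", "P", "", "", "protein", "taxon:9606", "20130101", "FTC", "", "",
    ]
    return "\t".join(fields) + "\n"


def test_parse_gaf_retains_regulator_annotation(tmp_path, toy_graph):
    gaf = tmp_path / "a.gaf"
    gaf.write_text(GAF_HEADER + _gaf_row("P00734", "GO:0030194"))
    result = parse_gaf(str(gaf), toy_graph)
    assert [(a.protein_id, a.term_id) for a in result] == [("P00734", "GO:0030194")]


def test_parse_gaf_drops_not_and_unknown(tmp_path, toy_graph):
    gaf = tmp_path / "a.gaf"
    gaf.write_text(
        GAF_HEADER
        + _gaf_row("P1", "GO:0007596", qualifier="NOT")
        + _gaf_row("P2", "GO:9999999")
        + _gaf_row("P3", "GO:0007596")
    )
    result = parse_gaf(str(gaf), toy_graph)
    assert len(result) == 1
    assert result.dropped["not_qualifier"] == 1
    assert result.dropped["unknown_term"] == 1


def test_parse_gaf_evidence_filter(tmp_path, toy_graph):
    gaf = tmp_path / "a.gaf"
    gaf.write_text(
        GAF_HEADER
        + _gaf_row("P1", "GO:0007596", evidence="IEA")
        + _gaf_row("P2", "GO:0007596", evidence="IDA")
    )
    result = parse_gaf(str(gaf), toy_graph, exclude_evidence=["IEA"])
    assert [a.protein_id for a in result] == ["P2"]
    assert result.dropped["evidence"] == 1


def test_parse_gaf_bad_column_count(tmp_path, toy_graph):
    gaf = tmp_path / "a.gaf"
    gaf.write_text(GAF_HEADER + "UniProtKB\tP1\tonly three\n")
    with pytest.raises(ParseError, match="line 2"):
        parse_gaf(str(gaf), toy_graph)


TARGETS = (
    "drug_id\tdrug_name\tprotein_id\taction_term\n"
    "DB04898\tximelagatran\tP00734\tinhibitor\n"
    "DB04898\tximelagatran\tP00734\tinhibitor\n"
    "DB00001\tdrug-a\tP00001\tagonist\n"
    "DB00002\tdrug-b\tP00002\tbinder\n"
)


def test_parse_drug_targets_signs_and_dedup(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(TARGETS)
    drugs, links = parse_drug_targets(str(path))
    assert {d.drug_id for d in drugs} == {"DB04898", "DB00001", "DB00002"}
    by_drug = {l.drug_id: l for l in links}
    assert len(links) == 3  # duplicate row collapsed
    assert by_drug["DB04898"].sign == -1
    assert by_drug["DB00001"].sign == +1
    assert by_drug["DB00002"].sign == "unknown"


def test_parse_drug_targets_missing_column(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("drug_id\tprotein_id\naction missing\tx\n")
    with pytest.raises(ParseError, match="missing column"):
        parse_drug_targets(str(path))


def test_parse_drug_targets_order_independent(tmp_path):
    rows = TARGETS.splitlines()
    header, body = rows[0], rows[1:]
    shuffled = list(body)
    random.Random(0).shuffle(shuffled)
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.write_text("\n".join([header] + body) + "\n")
    b.write_text("\n".join([header] + shuffled) + "\n")
    drugs_a, links_a = parse_drug_targets(str(a))
    drugs_b, links_b = parse_drug_targets(str(b))
    assert set(links_a) == set(links_b)
    assert {d.drug_id for d in drugs_a} == {d.drug_id for d in drugs_b}


def test_parse_atc_roundtrip_and_validation(tmp_path):
    path = tmp_path / "atc.tsv"
    path.write_text("drug_id\tatc_code\nDB00015\tB01AD07\nDB00015\tB01\n")
    atc = parse_atc(str(path))
    assert atc["DB00015"].atc_codes == frozenset({"B01AD07", "B01"})
    bad = tmp_path / "bad.tsv"
    bad.write_text("drug_id\tatc_code\nDB00015\tB0X1AD07\n")
    with pytest.raises(OntologyValidationError, match="B0X1AD07"):
        parse_atc(str(bad))


def test_parse_evaluation_points(tmp_path):
    path = tmp_path / "points.tsv"
    path.write_text(
        "ftc_id\tatc_code\tcomment\nFTC_A0008900\tA02BC\tproton pump inhibitors\n"
    )
    points = parse_evaluation_points(str(path))
    assert len(points) == 1
    assert points[0].ftc_category_id == "FTC_A0008900"
    assert points[0].atc_codes == frozenset({"A02BC"})

    empty = tmp_path / "empty.tsv"
    empty.write_text("ftc_id\tatc_code\tcomment\n")
    assert parse_evaluation_points(str(empty)) == []


def test_write_outputs_roundtrip(tmp_path, toy_graph):
    build = classify(KnowledgeBase(toy_graph, [], [], []))
    paths = write_outputs(build, tmp_path / "out")
    reparsed = parse_obo(str(paths["taxonomy"]))
    assert set(reparsed.terms) == set(build.taxonomy.categories)
    assert {(e.child, e.parent) for e in reparsed.edges} == set(
        build.taxonomy.subclass_edges
    )


def test_metrics_category_count(tmp_path, toy_graph):
    build = classify(KnowledgeBase(toy_graph, [], [], []))
    assert build.metrics["n_categories"] == 2 * len(TOY_NON_REGULATION_TERMS)


def test_write_outputs_empty_build(tmp_path):
    from ftc.ontology_io import OntologyGraph

    build = classify(KnowledgeBase(OntologyGraph([], []), [], [], []))
    paths = write_outputs(build, tmp_path / "empty")
    assert paths["memberships"].read_text().splitlines() == [
        "drug_id\tcategory_id\tkind\tprovenance"
    ]
    assert parse_obo(str(paths["taxonomy"])) is not None
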