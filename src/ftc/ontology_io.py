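"""Readers, writers and the in-memory knowledge base.

The pipeline consumes four plain-text inputs: an ontology in OBO format
(GO or a GO-like DAG), protein-to-term annotations in GAF 2.x, a
drug-target table (TSV with an action term per link), and a drug-to-ATC
code table (TSV).  Everything is parsed into small frozen dataclasses and
assembled into a :class:`KnowledgeBase`, the single object the classifier
operates on.

All tabular files are UTF-8, tab-delimited; lines starting with ``#`` are
ignored.  GAF comment lines start with ``!`` per the GAF standard.
"""

from __future__ import annotations

import io
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
from Bio.UniProt import GOA

log = logging.getLogger(__name__)

#: Edge types the pipeline understands; anything else is dropped on parse.
RELATIONS = (
    "is_a",
    "part_of",
    "regulates",
    "positively_regulates",
    "negatively_regulates",
)

#: Relations along which annotations/subsumption propagate by default.
HIERARCHY_RELATIONS = ("is_a", "part_of")

#: Sign carried by each regulates-family relation.
REGULATES_SIGN = {
    "regulates": 0,
    "positively_regulates": +1,
    "negatively_regulates": -1,
}

TERM_ID_RE = re.compile(r"^[A-Za-z]+[:_][A-Za-z0-9_]+$")
ATC_LEVEL_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

NAMESPACES = ("biological_process", "molecular_function", "other")


class ParseError(ValueError):
    """Malformed input file."""


class OntologyValidationError(ValueError):
    """Structurally invalid ontology (unknown endpoints, cycles, bad ids)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    label: str
    namespace: str = "other"
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not TERM_ID_RE.match(self.term_id):
            raise OntologyValidationError(f"malformed term id: {self.term_id!r}")
        if not self.obsolete and not self.label:
            raise OntologyValidationError(f"non-obsolete term {self.term_id} has no label")


@dataclass(frozen=True)
class OntologyEdge:
    child: str
    parent: str
    relation: str

    def __post_init__(self) -> None:
        if self.child == self.parent:
            raise OntologyValidationError(f"self-edge on {self.child}")
        if self.relation not in RELATIONS:
            raise OntologyValidationError(f"unknown relation {self.relation!r}")


class OntologyGraph:
    """Typed DAG of ontology terms.

    The subgraph restricted to is_a/part_of edges must be acyclic (this is
    checked at construction); regulates-family edges carry the polarity
    signs that the classifier composes.
    """

    def __init__(self, terms: Iterable[OntologyTerm], edges: Iterable[OntologyEdge]):
        self.terms: dict[str, OntologyTerm] = {t.term_id: t for t in terms}
        self.edges: list[OntologyEdge] = sorted(
            edges, key=lambda e: (e.child, e.parent, e.relation)
        )
        self._regulates_out: dict[str, list[tuple[str, int]]] = {}
        self._hierarchy = nx.DiGraph()
        self._hierarchy.add_nodes_from(self.terms)
        for e in self.edges:
            if e.child not in self.terms or e.parent not in self.terms:
                raise OntologyValidationError(
                    f"edge {e.child} -> {e.parent} references an unknown term"
                )
            if e.relation in REGULATES_SIGN:
                self._regulates_out.setdefault(e.child, []).append(
                    (e.parent, REGULATES_SIGN[e.relation])
                )
            else:
                self._hierarchy.add_edge(e.child, e.parent, relation=e.relation)
        if not nx.is_directed_acyclic_graph(self._hierarchy):
            cycle = nx.find_cycle(self._hierarchy)
            raise OntologyValidationError(
                f"is_a/part_of cycle involving {cycle[0][0]}"
            )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def regulates_out(self, term_id: str) -> list[tuple[str, int]]:
        """Signed regulates-family out-edges of a term."""
        return self._regulates_out.get(term_id, [])

    def is_regulation_term(self, term_id: str) -> bool:
        """True when the term carries at least one regulates-family edge."""
        return bool(self._regulates_out.get(term_id))

    def hierarchy_parents(
        self, term_id: str, relations: Sequence[str] = HIERARCHY_RELATIONS
    ) -> list[str]:
        return [
            p
            for p in self._hierarchy.successors(term_id)
            if self._hierarchy.edges[term_id, p]["relation"] in relations
        ]

    def ancestors(
        self, term_id: str, relations: Sequence[str] = HIERARCHY_RELATIONS
    ) -> set[str]:
        """Proper ancestors along the given hierarchy relations."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            for p in self.hierarchy_parents(stack.pop(), relations):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen


@dataclass(frozen=True)
class ProteinAnnotation:
    protein_id: str
    term_id: str
    evidence_code: str = ""
    qualifier: str = ""


@dataclass(frozen=True)
class Drug:
    drug_id: str
    name: str = ""


#: Sign value for action terms outside the mapping table.
UNKNOWN = "unknown"


@dataclass(frozen=True)
class PerturbationLink:
    drug_id: str
    protein_id: str
    action_term: str
    sign: object  # +1, -1 or UNKNOWN


@dataclass(frozen=True)
class AtcAnnotation:
    drug_id: str
    atc_codes: frozenset[str]


@dataclass(frozen=True)
class EvaluationPoint:
    ftc_category_id: str
    atc_codes: frozenset[str]
    comment: str = ""


@dataclass
class KnowledgeBase:
    """Everything the classifier needs: ontology, annotations, drugs, links."""

    graph: OntologyGraph
    annotations: list[ProteinAnnotation]
    drugs: list[Drug]
    links: list[PerturbationLink]

    def validate(self) -> None:
        drug_ids = {d.drug_id for d in self.drugs}
        for ann in self.annotations:
            if ann.term_id not in self.graph:
                raise OntologyValidationError(
                    f"annotation references unknown term {ann.term_id}"
                )
        for link in self.links:
            if link.drug_id not in drug_ids:
                raise OntologyValidationError(
                    f"link references unknown drug {link.drug_id}"
                )

    def annotations_by_protein(self) -> dict[str, list[ProteinAnnotation]]:
        out: dict[str, list[ProteinAnnotation]] = {}
        for ann in self.annotations:
            out.setdefault(ann.protein_id, []).append(ann)
        return out


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def _normalise_namespace(ns: str | None) -> str:
    return ns if ns in NAMESPACES[:2] else "other"


def parse_obo(path) -> OntologyGraph:
    """Read an OBO 1.2/1.4 ontology into an :class:`OntologyGraph`.

    Obsolete terms are recorded but stripped of edges and never anchor
    categories downstream.  Relations outside the five recognised types
    are dropped with a warning.
    """
    try:
        g = obonet.read_obo(path, ignore_obsolete=False)
    except OSError:
        raise
    except Exception as exc:  # obonet raises ValueError on bad stanzas
        raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc

    terms = []
    obsolete_ids = set()
    for node, data in g.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        if obsolete:
            obsolete_ids.add(node)
        terms.append(
            OntologyTerm(
                term_id=node,
                label=data.get("name", ""),
                namespace=_normalise_namespace(data.get("namespace")),
                obsolete=obsolete,
            )
        )
    edges = []
    dropped = Counter()
    for child, parent, rel in g.edges(keys=True):
        if rel not in RELATIONS:
            dropped[rel] += 1
            continue
        if child in obsolete_ids or parent in obsolete_ids:
            dropped["obsolete_endpoint"] += 1
            continue
        edges.append(OntologyEdge(child, parent, rel))
    for rel, n in dropped.items():
        log.warning("parse_obo: dropped %d edge(s) of unsupported kind %r", n, rel)
    return OntologyGraph(terms, edges)


@dataclass
class GafParse:
    """Retained annotations plus drop accounting."""

    annotations: list[ProteinAnnotation]
    dropped: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)


def parse_gaf(path, graph: OntologyGraph, exclude_evidence: Sequence[str] = ()) -> GafParse:
    """Read protein-to-term annotations from a GAF 2.x file.

    Rows whose qualifier contains NOT, whose term is absent from the
    graph, or whose evidence code is in ``exclude_evidence`` are dropped
    and counted in the result's ``dropped`` counter.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    n_cols = None
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("!"):
            continue
        width = len(line.split("\t"))
        if width not in (15, 17):
            raise ParseError(f"{path}: line {lineno}: expected 15 or 17 columns, got {width}")
        if n_cols is None:
            n_cols = width
    if n_cols is None:
        return GafParse([])

    exclude = {c.strip().upper() for c in exclude_evidence if c.strip()}
    result = GafParse([])
    with io.StringIO(text) as handle:
        for rec in GOA.gafiterator(handle):
            qualifier = "|".join(rec["Qualifier"]).strip("|")
            if any(q == "NOT" or q.startswith("NOT|") for q in rec["Qualifier"]):
                result.dropped["not_qualifier"] += 1
                continue
            if rec["GO_ID"] not in graph:
                result.dropped["unknown_term"] += 1
                continue
            if rec["Evidence"].upper() in exclude:
                result.dropped["evidence"] += 1
                continue
            result.annotations.append(
                ProteinAnnotation(
                    protein_id=rec["DB_Object_ID"],
                    term_id=rec["GO_ID"],
                    evidence_code=rec["Evidence"],
                    qualifier=qualifier,
                )
            )
    return result


def _read_tsv(path, required: Sequence[str]) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in required if c not in header]
                if missing:
                    raise ParseError(f"{path}: missing column(s) {missing}")
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise ParseError(f"{path}: empty file (no header)")
    return rows


def parse_drug_targets(path) -> tuple[list[Drug], list[PerturbationLink]]:
    """Read the drug-target TSV (drug_id, drug_name, protein_id, action_term).

    Duplicate (drug, protein, action) rows are collapsed; signs are
    resolved through :func:`ftc.classifier.map_action_to_sign`.
    """
    from .classifier import map_action_to_sign  # local: avoids import cycle

    rows = _read_tsv(path, ["drug_id", "drug_name", "protein_id", "action_term"])
    drugs: dict[str, Drug] = {}
    links: dict[tuple[str, str, str], PerturbationLink] = {}
    for row in rows:
        drugs.setdefault(row["drug_id"], Drug(row["drug_id"], row["drug_name"]))
        action = row["action_term"].strip().lower()
        key = (row["drug_id"], row["protein_id"], action)
        if key not in links:
            links[key] = PerturbationLink(
                drug_id=row["drug_id"],
                protein_id=row["protein_id"],
                action_term=action,
                sign=map_action_to_sign(action),
            )
    return list(drugs.values()), list(links.values())


def validate_atc_code(code: str) -> str:
    """Accept a full 7-character ATC code or any standard truncation level."""
    code = code.strip()
    if not ATC_LEVEL_RE.match(code):
        raise OntologyValidationError(f"malformed ATC code: {code!r}")
    return code


def parse_atc(path) -> dict[str, AtcAnnotation]:
    """Read drug-to-ATC rows (drug_id, atc_code; one row per code)."""
    rows = _read_tsv(path, ["drug_id", "atc_code"])
    codes: dict[str, set[str]] = {}
    for row in rows:
        codes.setdefault(row["drug_id"], set()).add(validate_atc_code(row["atc_code"]))
    return {
        drug: AtcAnnotation(drug, frozenset(cs)) for drug, cs in sorted(codes.items())
    }


def parse_evaluation_points(path) -> list[EvaluationPoint]:
    """Read curated FTC-to-ATC equivalences (ftc_id, atc_code, comment)."""
    from .core import parse_category_id  # local: avoids import cycle

    rows = _read_tsv(path, ["ftc_id", "atc_code"])
    grouped: dict[str, dict] = {}
    for row in rows:
        parse_category_id(row["ftc_id"])  # raises on malformed id
        entry = grouped.setdefault(row["ftc_id"], {"codes": set(), "comment": ""})
        entry["codes"].add(validate_atc_code(row["atc_code"]))
        if row.get("comment"):
            entry["comment"] = row["comment"]
    return [
        EvaluationPoint(fid, frozenset(e["codes"]), e["comment"])
        for fid, e in sorted(grouped.items())
    ]


def load_knowledge_base(
    obo_path, gaf_path, targets_path, exclude_evidence: Sequence[str] = ()
) -> KnowledgeBase:
    """Parse the three core inputs and assemble a validated knowledge base."""
    graph = parse_obo(obo_path)
    gaf = parse_gaf(gaf_path, graph, exclude_evidence=exclude_evidence)
    drugs, links = parse_drug_targets(targets_path)
    kb = KnowledgeBase(graph, gaf.annotations, drugs, links)
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_obo(graph: OntologyGraph, path, ontology_name: str = "synthetic-go") -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("format-version: 1.2\n")
        out.write(f"ontology: {ontology_name}\n")
        for term_id in sorted(graph.terms):
            term = graph.terms[term_id]
            out.write(f"\n[Term]\nid: {term.term_id}\nname: {term.label}\n")
            if term.namespace != "other":
                out.write(f"namespace: {term.namespace}\n")
            if term.obsolete:
                out.write("is_obsolete: true\n")
            for e in graph.edges:
                if e.child != term_id:
                    continue
                if e.relation == "is_a":
                    out.write(f"is_a: {e.parent}\n")
                else:
                    out.write(f"relationship: {e.relation} {e.parent}\n")


def write_gaf(annotations: Iterable[ProteinAnnotation], path, taxon: str = "taxon:9606") -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("!gaf-version: 2.1\n")
        for ann in annotations:
            fields = [
                "UniProtKB",
                ann.protein_id,
                ann.protein_id,
                ann.qualifier,
                ann.term_id,
                "PMID:0",
                ann.evidence_code or "IDA",
                "",
                "P",
                "",
                "",
                "protein",
                taxon,
                "20130101",
                "FTC",
                "",
                "",
            ]
            out.write("\t".join(fields) + "\n")


def write_drug_targets(
    drugs: Iterable[Drug], links: Iterable[PerturbationLink], path
) -> None:
    names = {d.drug_id: d.name for d in drugs}
    with open(path, "w", encoding="utf-8") as out:
        out.write("drug_id\tdrug_name\tprotein_id\taction_term\n")
        for link in links:
            out.write(
                f"{link.drug_id}\t{names.get(link.drug_id, '')}\t"
                f"{link.protein_id}\t{link.action_term}\n"
            )


def write_atc(atc: Mapping[str, AtcAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("drug_id\tatc_code\n")
        for drug_id in sorted(atc):
            for code in sorted(atc[drug_id].atc_codes):
                out.write(f"{drug_id}\t{code}\n")


def write_evaluation_points(points: Iterable[EvaluationPoint], path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("ftc_id\tatc_code\tcomment\n")
        for point in points:
            for code in sorted(point.atc_codes):
                out.write(f"{point.ftc_category_id}\t{code}\t{point.comment}\n")


def write_outputs(build, out_dir) -> dict[str, Path]:
    """Write a completed build: taxonomy OBO, memberships TSV, metrics JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": out_dir / "taxonomy.obo",
        "memberships": out_dir / "memberships.tsv",
        "metrics": out_dir / "metrics.json",
    }

    tax = build.taxonomy
    terms = [
        OntologyTerm(cat.category_id, cat.label, cat.namespace)
        for cat in tax.categories.values()
    ]
    edges = [OntologyEdge(c, p, "is_a") for c, p in tax.subclass_edges]
    write_obo(OntologyGraph(terms, edges), paths["taxonomy"], ontology_name="ftc")

    with open(paths["memberships"], "w", encoding="utf-8") as out:
        out.write("drug_id\tcategory_id\tkind\tprovenance\n")
        for m in build.memberships:
            out.write(
                f"{m.drug_id}\t{m.category_id}\t{m.kind}\t{';'.join(m.provenance)}\n"
            )

    with open(paths["metrics"], "w", encoding="utf-8") as out:
        json.dump(build.metrics, out, indent=2, sort_keys=True)
        out.write("\n")
    return paths
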