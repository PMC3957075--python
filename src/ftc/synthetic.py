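"""Seeded toy knowledge bases with planted, constructively-known truth.

The generator builds a GO-like DAG (rank-layered, hence acyclic by
construction), sprinkles regulation terms with signed regulates edges,
annotates proteins, and links drugs to proteins with signed actions.  The
expected direct memberships are recorded *while planting the chains*, from
the generator's own bookkeeping — never by running the classifier — so the
classifier can be falsified against them.

Optionally, drugs are grouped into clusters sharing a core target set and
an ATC class, which plants the within-class similarity structure the
permutation test is supposed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology_io import (
    AtcAnnotation,
    Drug,
    KnowledgeBase,
    OntologyEdge,
    OntologyGraph,
    OntologyTerm,
    PerturbationLink,
    ProteinAnnotation,
    write_atc,
    write_drug_targets,
    write_gaf,
    write_obo,
)

# Actions the generator plants, with the signs it knows it planted.
# ("binder" is deliberately outside the classifier's vocabulary: inert.)
_PLANTED_ACTION_SIGNS: dict[str, int | None] = {
    "inhibitor": -1,
    "antagonist": -1,
    "agonist": +1,
    "activator": +1,
    "binder": None,
}

_ATC_LETTERS = "ABCDGHJLMNPRSV"


class FixtureError(ValueError):
    """Infeasible fixture specification."""


@dataclass
class FixtureSpec:
    seed: int = 0
    n_terms: int = 30
    regulation_fraction: float = 0.25
    n_proteins: int = 10
    n_drugs: int = 8
    links_per_drug: int = 2
    annotations_per_protein: int = 2
    #: planted clusters: k groups of drugs sharing core targets + ATC class
    n_clusters: int = 0
    cluster_size: int = 3
    cluster_targets: int = 2
    #: extra random links given to cluster drugs on top of their shared core
    cluster_noise_links: int = 0
    mf_fraction: float = 0.2

    def validate(self) -> None:
        if self.n_terms < 1:
            raise FixtureError("need at least one term")
        if not 0.0 <= self.regulation_fraction <= 1.0:
            raise FixtureError("regulation_fraction must be in [0, 1]")
        if min(self.n_proteins, self.n_drugs, self.links_per_drug) < 0:
            raise FixtureError("sizes must be non-negative")
        n_base = self.n_terms - int(round(self.n_terms * self.regulation_fraction))
        if n_base < 1:
            raise FixtureError(
                "regulation_fraction leaves no base terms to regulate"
            )
        if self.n_clusters:
            if self.n_clusters * self.cluster_size > self.n_drugs:
                raise FixtureError("clusters need more drugs than available")
            if self.n_clusters * self.cluster_targets > n_base:
                raise FixtureError("clusters need more base terms than available")


@dataclass
class GroundTruth:
    """Planted expectations, recorded during generation."""

    direct: dict[str, frozenset[str]] = field(default_factory=dict)
    atc_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticKB:
    spec: FixtureSpec
    kb: KnowledgeBase
    atc: dict[str, AtcAnnotation]
    ground_truth: GroundTruth

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": out_dir / "ontology.obo",
            "gaf": out_dir / "annotations.gaf",
            "targets": out_dir / "drug_targets.tsv",
            "atc": out_dir / "atc.tsv",
        }
        write_obo(self.kb.graph, paths["obo"])
        write_gaf(self.kb.annotations, paths["gaf"])
        write_drug_targets(self.kb.drugs, self.kb.links, paths["targets"])
        write_atc(self.atc, paths["atc"])
        return paths


def _ftc_id(term_id: str, sign: int) -> str:
    # constructive id formatting, independent of ftc.core
    numeric = int(term_id.split(":")[1])
    return f"FTC_{'P' if sign > 0 else 'A'}{numeric:07d}"


def make_figure1_fixture() -> SyntheticKB:
    """The minimal worked example: one inhibitor of a coagulation activator.

    Ximelagatran inhibits prothrombin; prothrombin is annotated to
    'positive regulation of blood coagulation', which positively regulates
    'blood coagulation'.  Planted truth: one direct membership, in
    'Anti-blood coagulation agent' (sign algebra: -1 * +1 = ANTI).
    """
    terms = [
        OntologyTerm("GO:0007596", "blood coagulation", "biological_process"),
        OntologyTerm(
            "GO:0030194", "positive regulation of blood coagulation", "biological_process"
        ),
    ]
    edges = [OntologyEdge("GO:0030194", "GO:0007596", "positively_regulates")]
    graph = OntologyGraph(terms, edges)
    annotations = [ProteinAnnotation("P00734", "GO:0030194", "IDA")]
    drugs = [Drug("DB04898", "ximelagatran")]
    links = [PerturbationLink("DB04898", "P00734", "inhibitor", -1)]
    kb = KnowledgeBase(graph, annotations, drugs, links)
    truth = GroundTruth(direct={"DB04898": frozenset({_ftc_id("GO:0007596", -1)})})
    spec = FixtureSpec(seed=0, n_terms=2, regulation_fraction=0.5, n_proteins=1, n_drugs=1)
    return SyntheticKB(spec, kb, atc={}, ground_truth=truth)


def generate_random_kb(spec: FixtureSpec) -> SyntheticKB:
    """Seeded random knowledge base with planted ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_reg = int(round(spec.n_terms * spec.regulation_fraction))
    n_base = spec.n_terms - n_reg

    terms: list[OntologyTerm] = []
    edges: list[OntologyEdge] = []
    base_ids: list[str] = []
    namespaces: dict[str, str] = {}

    # rank-layered base terms: parents only among lower-ranked, same namespace
    for i in range(n_base):
        term_id = f"GO:{i + 1:07d}"
        ns = (
            "molecular_function"
            if rng.random() < spec.mf_fraction
            else "biological_process"
        )
        label = f"{'function' if ns == 'molecular_function' else 'process'} {i + 1}"
        terms.append(OntologyTerm(term_id, label, ns))
        namespaces[term_id] = ns
        candidates = [t for t in base_ids if namespaces[t] == ns]
        if candidates:
            n_parents = min(len(candidates), int(rng.integers(1, 3)))
            chosen = rng.choice(len(candidates), size=n_parents, replace=False)
            for j in sorted(chosen):
                relation = "part_of" if rng.random() < 0.2 else "is_a"
                edges.append(OntologyEdge(term_id, candidates[j], relation))
        base_ids.append(term_id)

    # regulation terms, one signed regulates edge each onto a base term
    reg_info: dict[str, tuple[str, int]] = {}
    sign_words = {1: "positive regulation of", -1: "negative regulation of", 0: "regulation of"}
    sign_rel = {
        1: "positively_regulates",
        -1: "negatively_regulates",
        0: "regulates",
    }
    for i in range(n_reg):
        term_id = f"GO:{n_base + i + 1:07d}"
        target = base_ids[int(rng.integers(0, n_base))]
        sign = int(rng.choice([1, -1, 0], p=[0.45, 0.45, 0.1]))
        target_label = next(t.label for t in terms if t.term_id == target)
        terms.append(
            OntologyTerm(
                term_id, f"{sign_words[sign]} {target_label}", namespaces[target]
            )
        )
        edges.append(OntologyEdge(term_id, target, sign_rel[sign]))
        reg_info[term_id] = (target, sign)

    graph = OntologyGraph(terms, edges)
    all_term_ids = [t.term_id for t in terms]

    # proteins annotated to random terms
    ann_map: dict[str, list[str]] = {}
    annotations: list[ProteinAnnotation] = []
    for i in range(spec.n_proteins):
        protein = f"P{i + 1:05d}"
        k = int(rng.integers(1, spec.annotations_per_protein + 1))
        chosen = rng.choice(len(all_term_ids), size=min(k, len(all_term_ids)), replace=False)
        ann_map[protein] = [all_term_ids[j] for j in sorted(chosen)]
        for term in ann_map[protein]:
            annotations.append(ProteinAnnotation(protein, term, "IDA"))

    # planted clusters: dedicated proteins on dedicated base terms
    cluster_of: dict[str, int] = {}
    cluster_proteins: dict[int, list[str]] = {}
    if spec.n_clusters:
        core_terms = rng.choice(
            n_base, size=spec.n_clusters * spec.cluster_targets, replace=False
        )
        for c in range(spec.n_clusters):
            cluster_proteins[c] = []
            for j in range(spec.cluster_targets):
                protein = f"PC{c + 1:02d}{j + 1:02d}"
                term = base_ids[int(core_terms[c * spec.cluster_targets + j])]
                ann_map[protein] = [term]
                annotations.append(ProteinAnnotation(protein, term, "IDA"))
                cluster_proteins[c].append(protein)
        for idx in range(spec.n_clusters * spec.cluster_size):
            cluster_of[f"DB{idx + 1:05d}"] = idx // spec.cluster_size

    # drugs and perturbation links
    drugs: list[Drug] = []
    links: list[PerturbationLink] = []
    truth = GroundTruth()
    actions = list(_PLANTED_ACTION_SIGNS)
    protein_pool = [f"P{i + 1:05d}" for i in range(spec.n_proteins)]

    def expected_from_link(protein: str, sign: int | None) -> set[str]:
        if sign is None:
            return set()
        out: set[str] = set()
        for term in ann_map.get(protein, []):
            if term in reg_info:
                target, r = reg_info[term]
                if r != 0:
                    out.add(_ftc_id(target, sign * r))
            else:
                out.add(_ftc_id(term, sign))
        return out

    for i in range(spec.n_drugs):
        drug_id = f"DB{i + 1:05d}"
        drugs.append(Drug(drug_id, f"drug-{i + 1}"))
        expected: set[str] = set()
        planted: set[tuple[str, str]] = set()

        if drug_id in cluster_of:
            for protein in cluster_proteins[cluster_of[drug_id]]:
                links.append(PerturbationLink(drug_id, protein, "inhibitor", -1))
                planted.add((protein, "inhibitor"))
                expected |= expected_from_link(protein, -1)
            n_noise = spec.cluster_noise_links
        else:
            n_noise = spec.links_per_drug

        for _ in range(n_noise if protein_pool else 0):
            protein = protein_pool[int(rng.integers(0, len(protein_pool)))]
            action = actions[int(rng.integers(0, len(actions)))]
            if (protein, action) in planted:
                continue
            planted.add((protein, action))
            sign = _PLANTED_ACTION_SIGNS[action]
            links.append(
                PerturbationLink(
                    drug_id, protein, action, "unknown" if sign is None else sign
                )
            )
            expected |= expected_from_link(protein, sign)
        truth.direct[drug_id] = frozenset(expected)

    # ATC labels: one class per cluster; non-cluster drugs get their own
    # letters or stay unlabelled
    atc: dict[str, AtcAnnotation] = {}
    for drug in drugs:
        if drug.drug_id in cluster_of:
            letter = _ATC_LETTERS[cluster_of[drug.drug_id] % len(_ATC_LETTERS)]
            code = f"{letter}01AA{1 + cluster_of[drug.drug_id]:02d}"
        elif rng.random() < 0.75:
            letter = _ATC_LETTERS[int(rng.integers(0, len(_ATC_LETTERS)))]
            code = f"{letter}{rng.integers(1, 17):02d}AA{rng.integers(1, 100):02d}"
        else:
            truth.atc_labels[drug.drug_id] = "NoCategory"
            continue
        atc[drug.drug_id] = AtcAnnotation(drug.drug_id, frozenset({code}))
        truth.atc_labels[drug.drug_id] = code[:1]

    kb = KnowledgeBase(graph, annotations, drugs, links)
    kb.validate()
    return SyntheticKB(spec, kb, atc, truth)
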