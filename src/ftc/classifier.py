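"""Polarity-aware drug classification.

A drug is a direct member of "Pro-X agent" / "Anti-X agent" when some chain

    drug --(signed perturbation p)--> protein --(annotation)--> term T,
    T decomposes to regulation form (X, r)

satisfies polarity = p * r (with r = +1 for the DIRECT form, i.e. when the
annotated term is X itself).  Neutral regulation (r = 0) and unmapped
action terms (sign = unknown) never produce memberships.  Indirect
memberships are the taxonomy ancestors of the direct ones.

:func:`classify` is the production path; :func:`brute_force_oracle`
recomputes the same result by naive enumeration over the raw edge lists and
exists so the two can be checked against each other.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import (
    DIRECT,
    BuildConfig,
    FtcCategory,
    Polarity,
    Taxonomy,
    build_taxonomy,
    category_id,
    classify_regulation,
    generate_categories,
    root_category,
)
from .ontology_io import (
    REGULATES_SIGN,
    UNKNOWN,
    Drug,
    KnowledgeBase,
    OntologyGraph,
    PerturbationLink,
    ProteinAnnotation,
)

log = logging.getLogger(__name__)

#: Default action-term vocabulary.  Case-insensitive; extensible via
#: :class:`ftc.core.BuildConfig.action_signs`.  Unknown actions are inert.
DEFAULT_ACTION_SIGNS: dict[str, int] = {
    "inhibitor": -1,
    "antagonist": -1,
    "blocker": -1,
    "suppressor": -1,
    "negative modulator": -1,
    "agonist": +1,
    "activator": +1,
    "inducer": +1,
    "stimulator": +1,
    "potentiator": +1,
    "positive modulator": +1,
}


def map_action_to_sign(action_term: str, table: Mapping[str, int] | None = None):
    """Resolve an action term to a perturbation sign (+1, -1 or 'unknown')."""
    table = DEFAULT_ACTION_SIGNS if table is None else table
    return table.get(action_term.strip().lower(), UNKNOWN)


@dataclass(frozen=True)
class MembershipAssignment:
    drug_id: str
    category_id: str
    kind: str  # "direct" | "indirect"
    provenance: tuple[str, ...] = ()

    def sort_key(self) -> tuple[str, str, str]:
        return (self.drug_id, self.category_id, self.kind)


@dataclass
class FtcBuild:
    """A classified knowledge base: taxonomy, memberships and metrics."""

    taxonomy: Taxonomy
    memberships: list[MembershipAssignment]
    drugs: list[Drug]
    metrics: dict = field(default_factory=dict)

    def memberships_by_drug(self, kind: str | None = None) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {d.drug_id: set() for d in self.drugs}
        for m in self.memberships:
            if kind is None or m.kind == kind:
                out.setdefault(m.drug_id, set()).add(m.category_id)
        return out

    def membership_pairs(self) -> set[tuple[str, str, str]]:
        return {(m.drug_id, m.category_id, m.kind) for m in self.memberships}

    def profile(self, drug_id: str, include_roots: bool = False) -> frozenset[str]:
        cats = {
            m.category_id
            for m in self.memberships
            if m.drug_id == drug_id
            and (include_roots or not self.taxonomy.is_root(m.category_id))
        }
        return frozenset(cats)


def _chain_string(
    link: PerturbationLink, ann: ProteinAnnotation, anchor: str, reg_sign
) -> str:
    reg = "direct" if reg_sign is DIRECT else f"reg{reg_sign:+d}"
    return (
        f"{link.drug_id}-[{link.action_term}:{link.sign:+d}]->{link.protein_id}"
        f"-[annotated]->{ann.term_id}-[{reg}]->{anchor}"
    )


def infer_direct_memberships(
    drugs: Sequence[Drug],
    links: Sequence[PerturbationLink],
    annotations: Sequence[ProteinAnnotation],
    graph: OntologyGraph,
    categories: Mapping[str, FtcCategory],
    config: BuildConfig | None = None,
) -> list[MembershipAssignment]:
    """Enumerate all satisfied membership patterns (kind=direct).

    Duplicate (drug, category) hits through different chains are merged,
    keeping every provenance chain.
    """
    config = config or BuildConfig()
    drug_ids = {d.drug_id for d in drugs}
    by_protein: dict[str, list[ProteinAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)

    provenance: dict[tuple[str, str], list[str]] = {}
    for link in links:
        if link.sign == UNKNOWN or link.drug_id not in drug_ids:
            continue
        anns = by_protein.get(link.protein_id)
        if not anns:
            log.debug("link %s -> %s: protein has no annotations", link.drug_id, link.protein_id)
            continue
        for ann in anns:
            for form in classify_regulation(ann.term_id, graph, config.regulation_chain_depth):
                if form.sign is DIRECT:
                    polarity = Polarity.from_sign(link.sign)
                elif form.sign == 0:
                    continue
                else:
                    polarity = Polarity.from_sign(link.sign * form.sign)
                cid = category_id(form.anchor, polarity)
                if cid not in categories:
                    continue
                provenance.setdefault((link.drug_id, cid), []).append(
                    _chain_string(link, ann, form.anchor, form.sign)
                )
    return [
        MembershipAssignment(drug, cid, "direct", tuple(sorted(set(chains))))
        for (drug, cid), chains in sorted(provenance.items())
    ]


def ancestor_closure(
    direct: Sequence[MembershipAssignment], taxonomy: Taxonomy
) -> list[MembershipAssignment]:
    """Indirect memberships: taxonomy ancestors of the direct set, minus it.

    Idempotent: the ancestor set of (direct + indirect) equals that of
    direct alone, because ancestor-of is transitive.
    """
    direct_by_drug: dict[str, set[str]] = {}
    for m in direct:
        direct_by_drug.setdefault(m.drug_id, set()).add(m.category_id)

    indirect: list[MembershipAssignment] = []
    for drug, cats in sorted(direct_by_drug.items()):
        inherited: dict[str, set[str]] = {}
        for cid in cats:
            for anc in taxonomy.ancestors(cid):
                inherited.setdefault(anc, set()).add(cid)
        for anc in sorted(set(inherited) - cats):
            prov = tuple(f"via {c}" for c in sorted(inherited[anc]))
            indirect.append(MembershipAssignment(drug, anc, "indirect", prov))
    return indirect


def _build_metrics(
    taxonomy: Taxonomy, memberships: Sequence[MembershipAssignment], kb: KnowledgeBase
) -> dict:
    n_categories = len(taxonomy.categories) - len(taxonomy.roots)
    direct_cats = {m.category_id for m in memberships if m.kind == "direct"}
    any_cats = {m.category_id for m in memberships}
    drugs_with_membership = {m.drug_id for m in memberships}
    return {
        "n_categories": n_categories,
        "n_roots": len(taxonomy.roots),
        "n_drugs": len(kb.drugs),
        "n_proteins": len({a.protein_id for a in kb.annotations}),
        "n_links": len(kb.links),
        "n_annotations": len(kb.annotations),
        "n_categories_direct": len(direct_cats),
        "n_categories_direct_or_indirect": len(any_cats),
        "frac_categories_direct": len(direct_cats) / n_categories if n_categories else 0.0,
        "frac_categories_any": len(any_cats) / n_categories if n_categories else 0.0,
        "n_drugs_classified": len(drugs_with_membership),
    }


def classify(kb: KnowledgeBase, config: BuildConfig | None = None) -> FtcBuild:
    """Full build: categories + taxonomy + direct/indirect memberships."""
    config = config or BuildConfig()
    kb.validate()
    t0 = time.perf_counter()
    categories = generate_categories(kb.graph, config)
    taxonomy = build_taxonomy(categories, kb.graph, config)
    direct = infer_direct_memberships(
        kb.drugs, kb.links, kb.annotations, kb.graph, categories, config
    )
    indirect = ancestor_closure(direct, taxonomy)
    memberships = sorted(direct + indirect, key=MembershipAssignment.sort_key)
    metrics = _build_metrics(taxonomy, memberships, kb)
    metrics["build_seconds"] = round(time.perf_counter() - t0, 4)
    log.info(
        "classified %d drugs into %d direct / %d indirect memberships in %.2fs",
        metrics["n_drugs"], len(direct), len(indirect), metrics["build_seconds"],
    )
    return FtcBuild(taxonomy, memberships, list(kb.drugs), metrics)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_oracle(kb: KnowledgeBase, config: BuildConfig | None = None) -> FtcBuild:
    """Re-derive the classification by naive enumeration over raw edges.

    Intentionally avoids the graph caches, :func:`classify_regulation` and
    the taxonomy object: regulation signs and subclass reachability are
    recomputed by exhaustive path search straight over ``kb.graph.edges``.
    Serves as an independent check of :func:`classify`.
    """
    config = config or BuildConfig()
    graph = kb.graph
    edges = graph.edges

    def reg_out(term):
        return [
            (e.parent, REGULATES_SIGN[e.relation])
            for e in edges
            if e.child == term and e.relation in REGULATES_SIGN
        ]

    def hier_out(term):
        return [
            e.parent
            for e in edges
            if e.child == term and e.relation in config.propagation_relations
        ]

    def signed_anchors(term, depth=0, sign=None):
        # all (anchor, composed sign) pairs reachable by <=depth regulates hops
        out = reg_out(term)
        if not out:
            yield (term, DIRECT if sign is None else sign)
            return
        if depth >= config.regulation_chain_depth:
            return
        for target, s in out:
            composed = s if sign is None else (0 if 0 in (sign, s) else sign * s)
            yield from signed_anchors(target, depth + 1, composed)

    def is_anchor(term):
        t = graph.terms[term]
        return (
            not t.obsolete
            and t.namespace in config.include_namespaces
            and not reg_out(term)
        )

    def anchor_ancestors(term):
        # anchors reachable upward via propagation relations (proper, naive BFS)
        seen, stack, found = set(), [term], set()
        while stack:
            for p in hier_out(stack.pop()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
                    if is_anchor(p):
                        found.add(p)
        return found

    anchors = sorted(t for t in graph.terms if is_anchor(t))
    categories = generate_categories(graph, config)
    taxonomy = build_taxonomy(categories, graph, config)

    by_protein: dict[str, list[ProteinAnnotation]] = {}
    for ann in kb.annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)

    direct_pairs: set[tuple[str, str]] = set()
    for drug in kb.drugs:
        for anchor in anchors:
            for polarity in (Polarity.PRO, Polarity.ANTI):
                satisfied = False
                for link in kb.links:
                    if link.drug_id != drug.drug_id or link.sign == UNKNOWN:
                        continue
                    for ann in by_protein.get(link.protein_id, []):
                        for a, r in signed_anchors(ann.term_id):
                            if a != anchor or r == 0:
                                continue
                            eff = link.sign if r is DIRECT else link.sign * r
                            if Polarity.from_sign(eff) is polarity:
                                satisfied = True
                if satisfied:
                    direct_pairs.add((drug.drug_id, category_id(anchor, polarity)))

    memberships = [
        MembershipAssignment(d, c, "direct", ("oracle",)) for d, c in sorted(direct_pairs)
    ]
    by_drug: dict[str, set[str]] = {}
    for d, c in direct_pairs:
        by_drug.setdefault(d, set()).add(c)
    for drug, cats in sorted(by_drug.items()):
        indirect: set[str] = set()
        for cid in cats:
            anchor, polarity = next(
                (c.anchor_term, c.polarity)
                for c in categories.values()
                if c.category_id == cid
            )
            ups = anchor_ancestors(anchor)
            indirect.update(category_id(a, polarity) for a in ups)
            # root is an ancestor of every category via its topmost anchors
            for top in {anchor} | ups:
                if not anchor_ancestors(top):
                    ns = graph.terms[top].namespace
                    indirect.add(root_category(polarity, ns).category_id)
        for cid in sorted(indirect - cats):
            memberships.append(MembershipAssignment(drug, cid, "indirect", ("oracle",)))

    memberships.sort(key=MembershipAssignment.sort_key)
    metrics = _build_metrics(taxonomy, memberships, kb)
    return FtcBuild(taxonomy, memberships, list(kb.drugs), metrics)


# ---------------------------------------------------------------------------
# polypharmacology
# ---------------------------------------------------------------------------


def polypharmacology_stats(build: FtcBuild) -> dict:
    """Per-drug MoA counts and their summary statistics.

    Counts mirror the resource's polypharmacology spectrum: 'direct' is the
    number of categories a drug satisfies definitionally, 'total' adds the
    inherited ancestor categories.
    """
    direct = build.memberships_by_drug("direct")
    total = build.memberships_by_drug(None)
    per_drug = [
        {
            "drug_id": d.drug_id,
            "direct": len(direct.get(d.drug_id, ())),
            "total": len(total.get(d.drug_id, ())),
        }
        for d in build.drugs
    ]
    classified = [row for row in per_drug if row["total"] > 0]

    def summary(key: str) -> dict:
        values = [row[key] for row in classified]
        if not values:
            return {"mean": 0.0, "min": 0, "max": 0, "range": 0}
        return {
            "mean": sum(values) / len(values),
            "min": min(values),
            "max": max(values),
            "range": max(values) - min(values),
        }

    return {
        "per_drug": per_drug,
        "direct": summary("direct"),
        "total": summary("total"),
        "n_drugs_classified": len(classified),
    }
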