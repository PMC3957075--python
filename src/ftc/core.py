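"""FTC categories, the polarity algebra and the category taxonomy.

Every non-obsolete, non-regulation biological-process or molecular-function
term X of the input ontology yields two mode-of-action categories:
"Pro-X agent" and "Anti-X agent".  Regulation terms ("positive regulation
of X", ...) are not reified as categories; instead their regulatory sign is
folded into the polarity when a drug's perturbation chain passes through
them.  The categories inherit the term hierarchy polarity-wise, giving a
DAG rooted in four abstract classes (Pro/Anti x process/function agent).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .ontology_io import HIERARCHY_RELATIONS, OntologyGraph

#: Sign marker for a term annotated directly (no regulates edge involved).
DIRECT = "direct"


class Polarity(enum.Enum):
    """Direction of a mode of action; closed under sign multiplication."""

    PRO = 1
    ANTI = -1

    def __mul__(self, other: "Polarity") -> "Polarity":
        return Polarity(self.value * other.value)

    @classmethod
    def from_sign(cls, sign: int) -> "Polarity":
        return cls(sign)

    @property
    def prefix(self) -> str:
        return "Pro" if self is Polarity.PRO else "Anti"

    @property
    def code(self) -> str:
        return "P" if self is Polarity.PRO else "A"


@dataclass(frozen=True)
class RegulationForm:
    """A term decomposed into (anchor process/function, regulatory sign).

    ``sign`` is +1/-1/0 when the term regulates the anchor (possibly through
    a chain of regulation terms, signs multiplied), or :data:`DIRECT` when
    the term is the anchor itself.
    """

    anchor: str
    sign: object  # +1, -1, 0 or DIRECT


def classify_regulation(
    term_id: str, graph: OntologyGraph, max_depth: int = 2
) -> frozenset[RegulationForm]:
    """Decompose a term into its regulation forms.

    A term with no regulates-family edge is its own anchor (DIRECT).  A
    regulation term contributes one form per regulated target; chains of
    regulation terms compose multiplicatively up to ``max_depth`` edges,
    with the neutral sign 0 absorbing (direction undeterminable).  Chains
    deeper than ``max_depth`` are dropped.
    """
    if term_id not in graph:
        raise KeyError(f"unknown term {term_id}")
    out = graph.regulates_out(term_id)
    if not out:
        return frozenset({RegulationForm(term_id, DIRECT)})

    forms: set[RegulationForm] = set()

    def walk(target: str, sign: int, depth: int) -> None:
        deeper = graph.regulates_out(target)
        if not deeper:
            forms.add(RegulationForm(target, sign))
            return
        if depth >= max_depth:
            return
        for nxt, s in deeper:
            walk(nxt, 0 if 0 in (sign, s) else sign * s, depth + 1)

    for target, sign in out:
        walk(target, sign, 1)
    return frozenset(forms)


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------

_CATEGORY_ID_RE = re.compile(r"^FTC_([PA])(\d{7})$")
_ROOT_ID_RE = re.compile(r"^FTC_([PA])_ROOT_(BP|MF)$")


def category_id(term_id: str, polarity: Polarity) -> str:
    """``GO:0008900`` + ANTI -> ``FTC_A0008900``."""
    numeric = re.sub(r"^[A-Za-z]+[:_]", "", term_id)
    if not numeric.isdigit():
        raise ValueError(f"term id {term_id!r} has no numeric part")
    return f"FTC_{polarity.code}{int(numeric):07d}"


def parse_category_id(cid: str, term_prefix: str = "GO") -> tuple[str, Polarity]:
    """Invert :func:`category_id`; root ids map to a pseudo-anchor."""
    m = _CATEGORY_ID_RE.match(cid)
    if m:
        polarity = Polarity.PRO if m.group(1) == "P" else Polarity.ANTI
        return f"{term_prefix}:{m.group(2)}", polarity
    m = _ROOT_ID_RE.match(cid)
    if m:
        polarity = Polarity.PRO if m.group(1) == "P" else Polarity.ANTI
        return f"ROOT:{m.group(2)}", polarity
    raise ValueError(f"malformed FTC category id: {cid!r}")


@dataclass(frozen=True)
class FtcCategory:
    category_id: str
    polarity: Polarity
    anchor_term: str | None  # None for the synthetic roots
    label: str
    namespace: str = "biological_process"


_ROOT_LABEL = {"biological_process": "biological process", "molecular_function": "molecular function"}
_ROOT_CODE = {"biological_process": "BP", "molecular_function": "MF"}


def root_category(polarity: Polarity, namespace: str) -> FtcCategory:
    """One of the four abstract roots, e.g. 'Anti-biological process agent'."""
    return FtcCategory(
        category_id=f"FTC_{polarity.code}_ROOT_{_ROOT_CODE[namespace]}",
        polarity=polarity,
        anchor_term=None,
        label=f"{polarity.prefix}-{_ROOT_LABEL[namespace]} agent",
        namespace=namespace,
    )


ROOT_CATEGORIES = tuple(
    root_category(pol, ns)
    for ns in ("biological_process", "molecular_function")
    for pol in (Polarity.PRO, Polarity.ANTI)
)


@dataclass
class BuildConfig:
    """Knobs of the category generator and classifier."""

    propagation_relations: tuple[str, ...] = tuple(HIERARCHY_RELATIONS)
    regulation_chain_depth: int = 2
    include_namespaces: tuple[str, ...] = ("biological_process", "molecular_function")
    action_signs: Mapping[str, int] | None = None  # None -> classifier default table


def generate_categories(
    graph: OntologyGraph, config: BuildConfig | None = None
) -> dict[str, FtcCategory]:
    """Two categories (PRO, ANTI) per eligible ontology term.

    Eligible: non-obsolete, in an included namespace, and not a regulation
    term (those fold into polarity instead of anchoring categories).
    """
    config = config or BuildConfig()
    categories: dict[str, FtcCategory] = {}
    for term_id, term in graph.terms.items():
        if term.obsolete or term.namespace not in config.include_namespaces:
            continue
        if graph.is_regulation_term(term_id):
            continue
        for polarity in (Polarity.PRO, Polarity.ANTI):
            cid = category_id(term_id, polarity)
            categories[cid] = FtcCategory(
                category_id=cid,
                polarity=polarity,
                anchor_term=term_id,
                label=f"{polarity.prefix}-{term.label} agent",
                namespace=term.namespace,
            )
    return categories


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """Category DAG: subclass edges (child, parent) plus the four roots."""

    categories: dict[str, FtcCategory]
    subclass_edges: list[tuple[str, str]]
    roots: list[str]
    _dag: nx.DiGraph = field(default_factory=nx.DiGraph, repr=False)

    def __post_init__(self) -> None:
        self._dag.add_nodes_from(self.categories)
        self._dag.add_edges_from(self.subclass_edges)
        if not nx.is_directed_acyclic_graph(self._dag):
            raise ValueError("taxonomy has a subclass cycle")

    def ancestors(self, cid: str) -> set[str]:
        """Proper ancestors (superclasses) of a category, roots included."""
        return set(nx.descendants(self._dag, cid))

    def parents(self, cid: str) -> set[str]:
        return set(self._dag.successors(cid))

    def is_root(self, cid: str) -> bool:
        return cid in self.roots


def build_taxonomy(
    categories: Mapping[str, FtcCategory],
    graph: OntologyGraph,
    config: BuildConfig | None = None,
) -> Taxonomy:
    """Lift the term hierarchy onto the categories, per polarity.

    Pro-X is a subclass of Pro-Y (and Anti-X of Anti-Y) exactly when Y is
    reachable from X along the propagation relations, after transitive
    reduction; anchors with no categorised ancestor attach to the matching
    polarity/namespace root.  Regulates-family edges never create subclass
    edges.
    """
    config = config or BuildConfig()
    anchors = sorted({c.anchor_term for c in categories.values() if c.anchor_term})
    for a in anchors:
        if a not in graph:
            raise ValueError(f"category anchor {a} is not in the ontology")

    # reachability among anchors (paths may pass through non-anchor terms)
    anchor_set = set(anchors)
    reach = nx.DiGraph()
    reach.add_nodes_from(anchors)
    for x in anchors:
        for y in graph.ancestors(x, config.propagation_relations):
            if y in anchor_set:
                reach.add_edge(x, y)
    reduced = nx.transitive_reduction(reach) if reach.edges else reach

    all_categories = dict(categories)
    roots = []
    namespaces = {graph.terms[a].namespace for a in anchors} or set()
    for root in ROOT_CATEGORIES:
        if root.namespace in namespaces or not anchors:
            all_categories[root.category_id] = root
            roots.append(root.category_id)

    edges: list[tuple[str, str]] = []
    for polarity in (Polarity.PRO, Polarity.ANTI):
        for x in anchors:
            parents = list(reduced.successors(x))
            if parents:
                edges.extend(
                    (category_id(x, polarity), category_id(y, polarity))
                    for y in sorted(parents)
                )
            else:
                ns = graph.terms[x].namespace
                edges.append(
                    (category_id(x, polarity), root_category(polarity, ns).category_id)
                )
    return Taxonomy(all_categories, sorted(edges), roots)
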