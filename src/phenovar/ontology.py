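"""Cross-species phenotype ontology construction.

Phenotype classes from human- and mouse-style vocabularies are decomposed
into the *phene pattern*: a phenotype P is an organism that ``has-part some
(E and has-quality some Q)`` where E is an affected entity (an anatomical
structure or a process) and Q a quality.  Raw definitional axioms are
rewritten into that pattern by a fixed set of per-relation rules; abstract
"structure-of" classes (S-classes) are generated for every affected entity
so that the phenotype hierarchy mirrors both the is-a and the part-of
structure of the underlying anatomy/physiology ontologies; zebrafish
phenotypes, which are annotated with entity and quality classes directly,
get one generated class per unique (E, Q[, E2]) combination.

Subsumption between phenotype classes is decided by a restricted reasoner
that covers exactly the fragment the rewriting rules produce: an
entity-closure test (is-a, plus part-of for S-classes and part-of-wrapped
entities) combined with a quality-closure test, with qualifier conjuncts
(modifier, towards, ...) required to be absent in the parent or to subsume
the child's.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

#: Universal top class (owl:Thing analogue); implicit superclass of every
#: entity and quality class.
TOP = "Thing"

#: Root of the inferred phenotype hierarchy: the phenotype of an organism
#: that has *some* part bearing *some* quality.
PHENOTYPE_ROOT = "PHENO:ROOT"

E_REPLACING_RELATIONS = ("inheres-in", "inheres-in-part-of")
E_EXTENDING_RELATIONS = (
    "towards",
    "has-quality",
    "exists-during",
    "part-of",
    "has-central-participant",
    "results-from",
    "occurs-in",
)
KNOWN_RELATIONS = frozenset(
    E_REPLACING_RELATIONS + E_EXTENDING_RELATIONS + ("modifier", "has-part")
)


class OntologyError(ValueError):
    """Raised for malformed ontologies, axioms, or definitions."""


class UnknownRelationError(OntologyError):
    pass


class UnresolvableFillerError(OntologyError):
    pass


# ---------------------------------------------------------------------------
# entity ontology
# ---------------------------------------------------------------------------


@dataclass
class EntityOntology:
    """Entity/quality/process classes with is-a and part-of edges.

    The union of both edge sets must form a DAG; every class is implicitly
    a subclass of :data:`TOP`.
    """

    classes: set[str]
    isa_edges: set[tuple[str, str]] = field(default_factory=set)
    partof_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for child, parent in list(self.isa_edges) + list(self.partof_edges):
            for c in (child, parent):
                if c not in self.classes and c != TOP:
                    raise OntologyError(f"edge endpoint {c!r} is not a declared class")
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        g.add_edges_from(self.isa_edges)
        g.add_edges_from(self.partof_edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"is-a/part-of cycle: {cycle}")
        self._anc_isa: dict[str, frozenset[str]] = {}
        self._anc_isa_partof: dict[str, frozenset[str]] = {}

    def has_class(self, cid: str) -> bool:
        return cid in self.classes or cid == TOP

    def _ancestors(self, cid: str, cache: dict, use_partof: bool) -> frozenset[str]:
        if cid in cache:
            return cache[cid]
        parents = [p for c, p in self.isa_edges if c == cid]
        if use_partof:
            parents += [p for c, p in self.partof_edges if c == cid]
        out = {cid, TOP}
        for p in parents:
            out |= self._ancestors(p, cache, use_partof)
        cache[cid] = frozenset(out)
        return cache[cid]

    def ancestors_isa(self, cid: str) -> frozenset[str]:
        """Reflexive-transitive is-a ancestors of ``cid`` (incl. TOP)."""
        if cid == TOP:
            return frozenset({TOP})
        if not self.has_class(cid):
            raise UnresolvableFillerError(f"unknown class {cid!r}")
        return self._ancestors(cid, self._anc_isa, use_partof=False)

    def ancestors_isa_partof(self, cid: str) -> frozenset[str]:
        """Reflexive-transitive ancestors over is-a ∪ part-of (incl. TOP)."""
        if cid == TOP:
            return frozenset({TOP})
        if not self.has_class(cid):
            raise UnresolvableFillerError(f"unknown class {cid!r}")
        return self._ancestors(cid, self._anc_isa_partof, use_partof=True)


# ---------------------------------------------------------------------------
# expressions and definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Expr:
    """A class expression: a base class, optionally wrapped in part-of,
    optionally extended by qualifier conjuncts ``(relation, filler)``."""

    base: str
    part_of: bool = False
    qualifiers: tuple[tuple[str, "Expr"], ...] = ()

    def normalized(self) -> "Expr":
        quals = tuple(sorted((r, f.normalized()) for r, f in self.qualifiers))
        return Expr(self.base, self.part_of, quals)

    def with_qualifier(self, relation: str, filler: "Expr") -> "Expr":
        return replace(self, qualifiers=self.qualifiers + ((relation, filler),))


TOP_EXPR = Expr(TOP)


@dataclass(frozen=True)
class EQDefinition:
    """A phenotype class in phene-pattern form.

    ``atoms`` holds one ``(E, Q)`` pair for a plain definition and several
    for an intersection arising from ``has-part`` conjuncts; a class with
    multiple atoms is subsumed by each conjunct's phenotype class.
    """

    phenotype_id: str
    atoms: tuple[tuple[Expr, Expr], ...]
    is_abstract: bool = False

    @property
    def entity(self) -> Expr:
        return self.atoms[0][0]

    @property
    def quality(self) -> Expr:
        return self.atoms[0][1]

    def normalized_atoms(self) -> tuple[tuple[Expr, Expr], ...]:
        return tuple(sorted((e.normalized(), q.normalized()) for e, q in self.atoms))


def _check_filler(filler, entities: EntityOntology) -> None:
    if isinstance(filler, str):
        if not entities.has_class(filler):
            raise UnresolvableFillerError(f"unresolvable filler {filler!r}")
    elif isinstance(filler, RawEQAxiom):
        for rel, f in filler.conjuncts:
            _check_filler(f, entities)
    else:
        raise UnresolvableFillerError(f"unresolvable filler {filler!r}")


@dataclass(frozen=True)
class RawEQAxiom:
    """A raw definitional axiom: an ordered list of (relation, filler)
    conjuncts; fillers are class IDs or nested :class:`RawEQAxiom`s."""

    phenotype_id: str
    conjuncts: tuple[tuple[str, object], ...]


def rewrite_axiom(raw: RawEQAxiom, entities: EntityOntology) -> EQDefinition:
    """Rewrite a raw definitional axiom into the phene pattern.

    E and Q start as the universal top class; conjuncts are applied
    left-to-right:

    * ``modifier X``            — attach as modifier of Q
    * ``inheres-in X``          — E ≔ X
    * ``inheres-in-part-of X``  — E ≔ part-of(X)
    * ``towards X``, ``exists-during X``, ``part-of X``,
      ``has-central-participant X``, ``results-from X``, ``occurs-in X``
      — extend E by the conjunct
    * ``has-quality X``         — sets Q while Q is still top (the genus
      quality of the definition); later occurrences extend E
    * ``has-part X1 ... Xn``    — intersection of recursively rewritten
      sub-definitions

    Unknown relations and unresolvable fillers are rejected by name.
    """
    e, q = TOP_EXPR, TOP_EXPR
    sub_atoms: list[tuple[Expr, Expr]] = []
    plain = False  # saw any non-has-part conjunct
    for relation, filler in raw.conjuncts:
        if relation not in KNOWN_RELATIONS:
            raise UnknownRelationError(f"unknown relation {relation!r}")
        _check_filler(filler, entities)
        if relation == "has-part":
            if isinstance(filler, str):
                filler = RawEQAxiom(raw.phenotype_id, (("inheres-in", filler),))
            sub = rewrite_axiom(filler, entities)
            sub_atoms.extend(sub.atoms)
            continue
        plain = True
        f = Expr(filler) if isinstance(filler, str) else _expr_of(filler, entities)
        if relation == "modifier":
            q = q.with_qualifier("modifier", f)
        elif relation == "inheres-in":
            e = Expr(f.base, qualifiers=f.qualifiers)
        elif relation == "inheres-in-part-of":
            e = Expr(f.base, part_of=True, qualifiers=f.qualifiers)
        elif relation == "has-quality" and q.base == TOP:
            q = replace(f, qualifiers=q.qualifiers + f.qualifiers)
        else:
            e = e.with_qualifier(relation, f)
    atoms: list[tuple[Expr, Expr]] = []
    if plain or not sub_atoms:
        atoms.append((e, q))
    atoms.extend(sub_atoms)
    return EQDefinition(raw.phenotype_id, tuple(atoms))


def _expr_of(nested: RawEQAxiom, entities: EntityOntology) -> Expr:
    d = rewrite_axiom(nested, entities)
    return d.entity


def _stable_id(prefix: str, payload: str) -> str:
    return f"{prefix}:{hashlib.sha1(payload.encode()).hexdigest()[:10]}"


def generate_abstract_class(entity: Expr | str) -> EQDefinition:
    """The abstract S-class for an entity: ``has-part some (part-of some E)``
    with the universal quality.  Deterministic ID; one class per distinct E.
    """
    e = Expr(entity) if isinstance(entity, str) else entity
    e = e.normalized()
    wrapped = replace(e, part_of=True)
    cid = _stable_id("S", repr(wrapped))
    return EQDefinition(cid, ((wrapped, TOP_EXPR),), is_abstract=True)


def make_zebrafish_class(
    e1: str, q: str, e2: str | None, entities: EntityOntology
) -> EQDefinition:
    """Generated class for a zebrafish annotation using E and Q directly;
    a second entity attaches to the quality as ``towards E2``."""
    for cid in (e1, q) + ((e2,) if e2 else ()):
        if not entities.has_class(cid):
            raise UnresolvableFillerError(f"unresolvable filler {cid!r}")
    quality = Expr(q)
    if e2 is not None:
        quality = quality.with_qualifier("towards", Expr(e2))
    e, quality = Expr(e1).normalized(), quality.normalized()
    cid = _stable_id("ZP", repr((e, quality)))
    return EQDefinition(cid, ((e, quality),))


# ---------------------------------------------------------------------------
# OBO-like input
# ---------------------------------------------------------------------------


def strip_disjointness(source) -> EntityOntology:
    """Parse an OBO-format entity/quality ontology, dropping every
    disjointness axiom and preserving is-a / part-of structure.

    ``source`` is a path or file-like object.  Returns the cleaned
    :class:`EntityOntology`; the number of removed disjointness axioms is
    recorded on the result as ``n_disjointness_removed``.
    """
    import obonet

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = obonet.read_obo(source, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - message shape varies
        raise OntologyError(f"cannot parse ontology source: {exc}") from exc
    classes = set(graph.nodes)
    if not classes:
        warnings.warn("empty ontology source", stacklevel=2)
    isa, partof = set(), set()
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            isa.add((child, parent))
        elif key == "part_of":
            partof.add((child, parent))
    n_disjoint = sum(len(d.get("disjoint_from", ())) for _, d in graph.nodes(data=True))
    ont = EntityOntology(classes=classes, isa_edges=isa, partof_edges=partof)
    ont.n_disjointness_removed = n_disjoint
    return ont


def read_axioms_tsv(path) -> list[RawEQAxiom]:
    """Read raw definitional axioms: TSV ``phenotype_id  relation  filler``,
    one conjunct per row, row order preserved.  Rows whose phenotype_id
    starts with ``_`` define nested expressions referenced as fillers."""
    import csv

    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["phenotype_id", "relation", "filler"]:
            raise OntologyError(f"unexpected axiom columns: {header}")
        for row in reader:
            if row:
                rows.append((row[0], row[1], row[2]))
    groups: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    for pid, rel, filler in rows:
        if pid not in groups:
            groups[pid] = []
            order.append(pid)
        groups[pid].append((rel, filler))

    def build(pid: str, stack: tuple[str, ...] = ()) -> RawEQAxiom:
        if pid in stack:
            raise OntologyError(f"cyclic nested expression {pid!r}")
        conjuncts = []
        for rel, filler in groups[pid]:
            if filler.startswith("_") and filler in groups:
                conjuncts.append((rel, build(filler, stack + (pid,))))
            else:
                conjuncts.append((rel, filler))
        return RawEQAxiom(pid, tuple(conjuncts))

    return [build(pid) for pid in order if not pid.startswith("_")]


# ---------------------------------------------------------------------------
# restricted reasoner
# ---------------------------------------------------------------------------


def _expr_subsumes(parent: Expr, child: Expr, entities: EntityOntology,
                   partof_closure: bool) -> bool:
    """Does ``parent`` subsume ``child`` in the restricted fragment?

    ``partof_closure`` selects the is-a ∪ part-of closure for the base test
    when the parent is part-of-wrapped (entity position); qualities never
    use part-of.
    """
    if parent.part_of:
        if parent.base != TOP and parent.base not in entities.ancestors_isa_partof(child.base):
            return False
    else:
        if parent.base == TOP:
            pass
        elif child.part_of:
            return False
        elif parent.base not in entities.ancestors_isa(child.base):
            return False
    # qualifier compatibility: each parent qualifier absent or subsuming
    for rel, pf in parent.qualifiers:
        if not any(
            rel == crel and _expr_subsumes(pf, cf, entities, partof_closure=False)
            for crel, cf in child.qualifiers
        ):
            return False
    return True


def _atom_subsumes(parent: tuple[Expr, Expr], child: tuple[Expr, Expr],
                   entities: EntityOntology) -> bool:
    pe, pq = parent
    ce, cq = child
    return _expr_subsumes(pe, ce, entities, partof_closure=pe.part_of) and _expr_subsumes(
        pq, cq, entities, partof_closure=False
    )


def definition_subsumes(parent: EQDefinition, child: EQDefinition,
                        entities: EntityOntology) -> bool:
    """Decide ``child ⊑ parent`` for phene-pattern definitions (intersection
    semantics: every parent atom must subsume some child atom)."""
    return all(
        any(_atom_subsumes(pa, ca, entities) for ca in child.atoms)
        for pa in parent.atoms
    )


@dataclass
class PhenotypeHierarchy:
    """The inferred subsumption DAG over phenotype classes.

    ``edges`` is the transitive reduction (child → parent); equivalent
    classes (mutual subsumption) are quotiented into groups with a
    canonical representative, and closure queries expand the groups.
    """

    nodes: set[str]
    edges: set[tuple[str, str]]
    root: str = PHENOTYPE_ROOT
    equivalences: dict[str, str] = field(default_factory=dict)  # member -> canonical
    definitions: dict[str, EQDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.nodes)
        self._graph.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(self._graph):
            raise OntologyError("phenotype hierarchy contains a cycle")
        self._groups: dict[str, set[str]] = {}
        for member, canon in self.equivalences.items():
            self._groups.setdefault(canon, {canon}).add(member)
        self._anc_cache: dict[str, frozenset[str]] = {}

    def has_class(self, cid: str) -> bool:
        return cid in self.nodes

    def ancestors(self, cid: str) -> frozenset[str]:
        """All classes subsuming ``cid`` (reflexive, incl. equivalents)."""
        if cid in self._anc_cache:
            return self._anc_cache[cid]
        if cid not in self.nodes:
            raise OntologyError(f"unknown phenotype class {cid!r}")
        reach = {cid} | nx.descendants(self._graph, cid)  # edges point child->parent
        out = set()
        for r in reach:
            canon = self.equivalences.get(r, r)
            out |= self._groups.get(canon, {r})
            out.add(r)
        fs = frozenset(out)
        self._anc_cache[cid] = fs
        return fs

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.ancestors(descendant)

    def subsumption_pairs(self) -> set[tuple[str, str]]:
        """The full (descendant, ancestor) relation, reflexive-transitive."""
        return {(c, a) for c in self.nodes for a in self.ancestors(c)}

    def children_of(self, cid: str) -> list[str]:
        return sorted(c for c, p in self.edges if p == cid)


def infer_hierarchy(
    definitions: Iterable[EQDefinition], entities: EntityOntology
) -> PhenotypeHierarchy:
    """Infer the phenotype subsumption hierarchy from phene-pattern
    definitions via the restricted reasoner.

    The universal phenotype root is added automatically; output edges are
    the transitive reduction of the subsumption partial order, with
    equivalence groups (mutual subsumption) quotiented out.
    """
    defs = {d.phenotype_id: d for d in definitions}
    if PHENOTYPE_ROOT not in defs:
        defs[PHENOTYPE_ROOT] = EQDefinition(PHENOTYPE_ROOT, ((TOP_EXPR, TOP_EXPR),))
    for d in defs.values():
        for e, q in d.atoms:
            for expr in (e, q):
                _validate_expr(expr, entities)
    ids = sorted(defs)
    sub: dict[str, set[str]] = {}  # child -> set of parents (strict+refl)
    for c in ids:
        sub[c] = {
            p for p in ids if definition_subsumes(defs[p], defs[c], entities)
        }
    # equivalence groups
    canon: dict[str, str] = {}
    for c in ids:
        group = sorted(x for x in sub[c] if c in sub[x])  # mutual
        canon[c] = group[0]
    equivalences = {c: k for c, k in canon.items() if c != k}
    # force the root to be canonical for its group
    if canon[PHENOTYPE_ROOT] != PHENOTYPE_ROOT:
        old = canon[PHENOTYPE_ROOT]
        for c, k in list(canon.items()):
            if k == old:
                canon[c] = PHENOTYPE_ROOT
        equivalences = {c: k for c, k in canon.items() if c != k}
    quotient = nx.DiGraph()
    quotient.add_nodes_from(set(canon.values()))
    for c in ids:
        for p in sub[c]:
            cc, cp = canon[c], canon[p]
            if cc != cp:
                quotient.add_edge(cc, cp)
    reduced = nx.transitive_reduction(quotient)
    edges = set(reduced.edges())
    for member, k in equivalences.items():
        edges.add((member, k))
    return PhenotypeHierarchy(
        nodes=set(ids),
        edges=edges,
        root=PHENOTYPE_ROOT,
        equivalences=equivalences,
        definitions=defs,
    )


def _validate_expr(expr: Expr, entities: EntityOntology) -> None:
    if not entities.has_class(expr.base):
        raise UnresolvableFillerError(f"unresolvable filler {expr.base!r}")
    for _, f in expr.qualifiers:
        _validate_expr(f, entities)


# ---------------------------------------------------------------------------
# build pipeline + serialization
# ---------------------------------------------------------------------------


def build_ontology(
    entities: EntityOntology,
    axioms: Sequence[RawEQAxiom],
    zebrafish_annotations: Sequence[tuple[str, str, str | None]] = (),
) -> tuple[PhenotypeHierarchy, dict[str, str]]:
    """Full construction: rewrite axioms, generate zebrafish classes and
    abstract S-classes, infer the hierarchy.

    Returns the hierarchy and a mapping from zebrafish annotation key
    ``(E1, Q, E2)`` rendered as ``E1|Q|E2`` to its generated class ID.
    """
    defs: dict[str, EQDefinition] = {}
    for raw in axioms:
        d = rewrite_axiom(raw, entities)
        defs[d.phenotype_id] = d
    zmap: dict[str, str] = {}
    for e1, q, e2 in zebrafish_annotations:
        d = make_zebrafish_class(e1, q, e2, entities)
        defs.setdefault(d.phenotype_id, d)
        zmap["|".join((e1, q, e2 or ""))] = d.phenotype_id
    # one abstract S-class per distinct entity expression
    for d in list(defs.values()):
        for e, _ in d.atoms:
            if e.base == TOP:
                continue
            s = generate_abstract_class(e)
            defs.setdefault(s.phenotype_id, s)
    hierarchy = infer_hierarchy(defs.values(), entities)
    return hierarchy, zmap


def write_hierarchy(hierarchy: PhenotypeHierarchy, out_dir) -> None:
    """Write the hierarchy as an edge-list TSV plus class metadata TSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "hierarchy_edges.tsv", "w") as fh:
        fh.write("child_id\tparent_id\n")
        for c, p in sorted(hierarchy.edges):
            fh.write(f"{c}\t{p}\n")
    with open(out / "classes.tsv", "w") as fh:
        fh.write("class_id\tis_abstract\tcanonical_id\n")
        for cid in sorted(hierarchy.nodes):
            d = hierarchy.definitions.get(cid)
            abstract = int(bool(d and d.is_abstract))
            fh.write(f"{cid}\t{abstract}\t{hierarchy.equivalences.get(cid, cid)}\n")


def read_hierarchy(out_dir) -> PhenotypeHierarchy:
    """Load a hierarchy written by :func:`write_hierarchy`."""
    from pathlib import Path

    out = Path(out_dir)
    edges, nodes, equiv = set(), set(), {}
    with open(out / "classes.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["class_id", "is_abstract", "canonical_id"]:
            raise OntologyError(f"unexpected class columns: {header}")
        for line in fh:
            cid, _, canon = line.rstrip("\n").split("\t")
            nodes.add(cid)
            if canon != cid:
                equiv[cid] = canon
    with open(out / "hierarchy_edges.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["child_id", "parent_id"]:
            raise OntologyError(f"unexpected edge columns: {header}")
        for line in fh:
            c, p = line.rstrip("\n").split("\t")
            edges.add((c, p))
    return PhenotypeHierarchy(nodes=nodes, edges=edges, equivalences=equiv)
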