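"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles against the stated
closure rules and formulas — naive BFS closures, exhaustive pairwise
decisions, direct set arithmetic — and deliberately shares no code with
the package internals it validates.
"""

from __future__ import annotations

import math

import numpy as np

from phenovar.ontology import TOP, EntityOntology, EQDefinition, Expr


# ---------------------------------------------------------------------------
# reachability (naive BFS; no caching, no networkx)
# ---------------------------------------------------------------------------


def bfs_ancestors(node: str, edges: set[tuple[str, str]]) -> set[str]:
    """Reflexive-transitive ancestors of ``node`` following child→parent
    edges, plus the universal top class."""
    seen = {node}
    stack = [node]
    while stack:
        cur = stack.pop()
        for c, p in edges:
            if c == cur and p not in seen:
                seen.add(p)
                stack.append(p)
    seen.add(TOP)
    return seen


def oracle_expr_subsumes(parent: Expr, child: Expr, ont: EntityOntology) -> bool:
    isa = set(ont.isa_edges)
    both = isa | set(ont.partof_edges)
    if parent.part_of:
        if parent.base != TOP and parent.base not in bfs_ancestors(child.base, both):
            return False
    else:
        if parent.base == TOP:
            pass
        elif child.part_of:
            return False
        elif parent.base not in bfs_ancestors(child.base, isa):
            return False
    for rel, pf in parent.qualifiers:
        matched = False
        for crel, cf in child.qualifiers:
            if crel == rel and oracle_expr_subsumes(pf, cf, ont):
                matched = True
                break
        if not matched:
            return False
    return True


def oracle_definition_subsumes(
    parent: EQDefinition, child: EQDefinition, ont: EntityOntology
) -> bool:
    for pe, pq in parent.atoms:
        if not any(
            oracle_expr_subsumes(pe, ce, ont) and oracle_expr_subsumes(pq, cq, ont)
            for ce, cq in child.atoms
        ):
            return False
    return True


def oracle_subsumption_pairs(
    defs: dict[str, EQDefinition], ont: EntityOntology
) -> set[tuple[str, str]]:
    """Exhaustive O(n^2) pairwise subsumption relation (child, parent)."""
    ids = list(defs)
    return {
        (c, p)
        for c in ids
        for p in ids
        if oracle_definition_subsumes(defs[p], defs[c], ont)
    }


# ---------------------------------------------------------------------------
# information content / similarity (direct set arithmetic over edge lists)
# ---------------------------------------------------------------------------


def oracle_ic(
    gene_annotations: dict[str, set[str]],
    nodes: set[str],
    edges: set[tuple[str, str]],
    root: str,
) -> dict[str, float]:
    n_total = len(gene_annotations)
    covered = {
        g: set().union(*(bfs_ancestors(p, edges) - {TOP} for p in annots))
        for g, annots in gene_annotations.items()
    }
    ic = {}
    for c in nodes:
        n_c = sum(1 for g in covered if c in covered[g])
        ic[c] = -math.log(max(n_c, 1) / n_total)
    ic[root] = 0.0
    return ic


def oracle_resnik(c1, c2, ic, edges) -> float:
    common = (bfs_ancestors(c1, edges) - {TOP}) & (bfs_ancestors(c2, edges) - {TOP})
    return max(ic[c] for c in common)


def oracle_bma(s1, s2, ic, edges) -> float:
    fwd = sum(max(oracle_resnik(a, b, ic, edges) for b in s2) for a in s1) / len(s1)
    rev = sum(max(oracle_resnik(a, b, ic, edges) for a in s1) for b in s2) / len(s2)
    return (fwd + rev) / 2


# ---------------------------------------------------------------------------
# ROC AUC (pairwise comparison estimator, ties counted 1/2)
# ---------------------------------------------------------------------------


def oracle_auc(y_true, scores) -> float:
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# random reasoner instances
# ---------------------------------------------------------------------------


def random_reasoner_instance(seed: int, n_entities: int = 40, n_defs: int = 60):
    """A random entity/quality ontology plus varied phene-pattern
    definitions (modifiers, towards, part-of wraps, abstract classes,
    zebrafish-style classes, occasional intersections)."""
    from phenovar.ontology import (
        RawEQAxiom,
        generate_abstract_class,
        make_zebrafish_class,
        rewrite_axiom,
    )

    rng = np.random.default_rng(seed)
    ents = [f"E{i}" for i in range(n_entities)]
    quals = [f"Q{i}" for i in range(8)]
    isa, partof = set(), set()
    for i in range(1, n_entities):
        isa.add((ents[i], ents[rng.integers(i)]))
        if rng.random() < 0.4:
            partof.add((ents[i], ents[rng.integers(i)]))
    for i in range(1, len(quals)):
        isa.add((quals[i], quals[rng.integers(i)]))
    ont = EntityOntology(
        classes=set(ents) | set(quals), isa_edges=isa, partof_edges=partof
    )
    defs: dict[str, EQDefinition] = {}
    for k in range(n_defs):
        e = ents[rng.integers(n_entities)]
        q = quals[rng.integers(len(quals))]
        r = rng.random()
        if r < 0.55:
            conjuncts = [("inheres-in", e), ("has-quality", q)]
            if rng.random() < 0.3:
                conjuncts.append(("modifier", quals[rng.integers(len(quals))]))
            if rng.random() < 0.25:
                conjuncts.append(("towards", ents[rng.integers(n_entities)]))
            d = rewrite_axiom(RawEQAxiom(f"P{k}", tuple(conjuncts)), ont)
        elif r < 0.70:
            conjuncts = [("inheres-in-part-of", e), ("has-quality", q)]
            d = rewrite_axiom(RawEQAxiom(f"P{k}", tuple(conjuncts)), ont)
        elif r < 0.80:
            e2 = ents[rng.integers(n_entities)] if rng.random() < 0.5 else None
            d = make_zebrafish_class(e, q, e2, ont)
        elif r < 0.90:
            d = generate_abstract_class(e)
        else:
            nested1 = RawEQAxiom("_a", (("inheres-in", e), ("has-quality", q)))
            nested2 = RawEQAxiom(
                "_b",
                (
                    ("inheres-in", ents[rng.integers(n_entities)]),
                    ("has-quality", quals[rng.integers(len(quals))]),
                ),
            )
            d = rewrite_axiom(
                RawEQAxiom(f"P{k}", (("has-part", nested1), ("has-part", nested2))),
                ont,
            )
        defs.setdefault(d.phenotype_id, d)
    return ont, defs
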