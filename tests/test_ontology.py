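"""Ontology construction: rewrite rules, generated classes, the restricted
reasoner, and its agreement with a brute-force closure oracle."""

from __future__ import annotations

import textwrap

import pytest

from phenovar.ontology import (
    PHENOTYPE_ROOT,
    TOP,
    EntityOntology,
    Expr,
    OntologyError,
    RawEQAxiom,
    UnknownRelationError,
    UnresolvableFillerError,
    build_ontology,
    generate_abstract_class,
    infer_hierarchy,
    make_zebrafish_class,
    read_axioms_tsv,
    read_hierarchy,
    rewrite_axiom,
    strip_disjointness,
    write_hierarchy,
)

from _oracles import oracle_subsumption_pairs, random_reasoner_instance


@pytest.fixture(scope="module")
def anatomy() -> EntityOntology:
    """LeftVentricle is-a HeartChamber part-of Heart is-a Organ; qualities
    Enlarged with child SeverelyEnlarged, plus Small and Abnormal."""
    return EntityOntology(
        classes={
            "Organ", "Heart", "HeartChamber", "LeftVentricle", "Limb",
            "Enlarged", "SeverelyEnlarged", "Small", "Abnormal", "Collagen",
            "Fin", "Malformed", "DecreasedAmount",
        },
        isa_edges={
            ("Heart", "Organ"),
            ("LeftVentricle", "HeartChamber"),
            ("SeverelyEnlarged", "Enlarged"),
        },
        partof_edges={("HeartChamber", "Heart")},
    )


class TestRewriteAxiom:
    def test_entity_and_quality_from_conjuncts(self, anatomy):
        d = rewrite_axiom(
            RawEQAxiom("P1", (("inheres-in", "Heart"), ("has-quality", "Enlarged"))),
            anatomy,
        )
        assert d.entity == Expr("Heart")
        assert d.quality == Expr("Enlarged")

    def test_empty_conjuncts_default_to_top(self, anatomy):
        d = rewrite_axiom(RawEQAxiom("P0", ()), anatomy)
        assert d.entity == Expr(TOP)
        assert d.quality == Expr(TOP)

    def test_inheres_in_part_of_wraps_entity_and_modifier_attaches(self, anatomy):
        d = rewrite_axiom(
            RawEQAxiom(
                "P2",
                (
                    ("inheres-in-part-of", "Limb"),
                    ("has-quality", "Small"),
                    ("modifier", "Abnormal"),
                ),
            ),
            anatomy,
        )
        assert d.entity == Expr("Limb", part_of=True)
        assert d.quality.base == "Small"
        assert ("modifier", Expr("Abnormal")) in d.quality.qualifiers

    def test_towards_extends_entity(self, anatomy):
        d = rewrite_axiom(
            RawEQAxiom(
                "P3",
                (
                    ("inheres-in", "Heart"),
                    ("has-quality", "Enlarged"),
                    ("towards", "Collagen"),
                ),
            ),
            anatomy,
        )
        assert ("towards", Expr("Collagen")) in d.entity.qualifiers

    def test_second_has_quality_extends_entity(self, anatomy):
        # the genus quality sets Q; a later has-quality conjunct attaches to E
        d = rewrite_axiom(
            RawEQAxiom(
                "P4",
                (
                    ("inheres-in", "Heart"),
                    ("has-quality", "Enlarged"),
                    ("has-quality", "Small"),
                ),
            ),
            anatomy,
        )
        assert d.quality.base == "Enlarged"
        assert ("has-quality", Expr("Small")) in d.entity.qualifiers

    def test_has_part_intersection_collects_atoms(self, anatomy):
        nested1 = RawEQAxiom("_a", (("inheres-in", "Heart"), ("has-quality", "Enlarged")))
        nested2 = RawEQAxiom("_b", (("inheres-in", "Limb"), ("has-quality", "Small")))
        d = rewrite_axiom(
            RawEQAxiom("P5", (("has-part", nested1), ("has-part", nested2))), anatomy
        )
        assert len(d.atoms) == 2
        bases = {e.base for e, _ in d.atoms}
        assert bases == {"Heart", "Limb"}

    def test_unknown_relation_rejected_by_name(self, anatomy):
        with pytest.raises(UnknownRelationError, match="part-of-sideways"):
            rewrite_axiom(
                RawEQAxiom("P6", (("part-of-sideways", "Heart"),)), anatomy
            )

    def test_unresolvable_filler_rejected_by_name(self, anatomy):
        with pytest.raises(UnresolvableFillerError, match="Spleen"):
            rewrite_axiom(RawEQAxiom("P7", (("inheres-in", "Spleen"),)), anatomy)


class TestGeneratedClasses:
    def test_abstract_class_shape(self):
        s = generate_abstract_class("Heart")
        assert s.is_abstract
        assert s.entity == Expr("Heart", part_of=True)
        assert s.quality == Expr(TOP)

    def test_abstract_class_idempotent_id(self):
        assert (
            generate_abstract_class("Heart").phenotype_id
            == generate_abstract_class("Heart").phenotype_id
        )
        assert (
            generate_abstract_class("Heart").phenotype_id
            != generate_abstract_class("Limb").phenotype_id
        )

    def test_abstract_class_over_top_is_equivalent_to_root(self, anatomy):
        s = generate_abstract_class(TOP)
        h = infer_hierarchy([s], anatomy)
        assert h.equivalences.get(s.phenotype_id) == PHENOTYPE_ROOT

    def test_zebrafish_single_entity(self, anatomy):
        d = make_zebrafish_class("Fin", "Malformed", None, anatomy)
        assert d.entity == Expr("Fin")
        assert d.quality == Expr("Malformed")

    def test_zebrafish_two_entities_attach_towards_to_quality(self, anatomy):
        d = make_zebrafish_class("Fin", "DecreasedAmount", "Collagen", anatomy)
        assert d.quality.base == "DecreasedAmount"
        assert ("towards", Expr("Collagen")) in d.quality.qualifiers

    def test_zebrafish_unique_combination_reuses_id(self, anatomy):
        a = make_zebrafish_class("Fin", "Malformed", None, anatomy)
        b = make_zebrafish_class("Fin", "Malformed", None, anatomy)
        c = make_zebrafish_class("Fin", "Small", None, anatomy)
        assert a.phenotype_id == b.phenotype_id != c.phenotype_id

    def test_zebrafish_undeclared_class_rejected(self, anatomy):
        with pytest.raises(UnresolvableFillerError):
            make_zebrafish_class("Fin", "Iridescent", None, anatomy)


class TestStripDisjointness:
    def test_disjointness_removed_other_axioms_kept(self, tmp_path):
        src = tmp_path / "ent.obo"
        src.write_text(
            textwrap.dedent(
                """\
                format-version: 1.2
                ontology: toy

                [Term]
                id: E:1
                name: heart
                is_a: E:0
                disjoint_from: E:2
                relationship: part_of E:3

                [Term]
                id: E:0
                name: organ

                [Term]
                id: E:2
                name: lung
                disjoint_from: E:1

                [Term]
                id: E:3
                name: thorax
                is_a: E:0
                """
            )
        )
        ont = strip_disjointness(str(src))
        assert ont.n_disjointness_removed == 2
        assert ont.isa_edges == {("E:1", "E:0"), ("E:3", "E:0")}
        assert ont.partof_edges == {("E:1", "E:3")}

    def test_source_without_disjointness_is_identity(self, tmp_path):
        src = tmp_path / "ent.obo"
        src.write_text(
            "format-version: 1.2\nontology: toy\n\n[Term]\nid: E:1\nname: x\n"
        )
        ont = strip_disjointness(str(src))
        assert ont.n_disjointness_removed == 0
        assert ont.classes == {"E:1"}

    def test_empty_source_warns(self, tmp_path):
        src = tmp_path / "ent.obo"
        src.write_text("format-version: 1.2\nontology: toy\n")
        with pytest.warns(UserWarning, match="empty"):
            ont = strip_disjointness(str(src))
        assert ont.classes == set()


class TestInferHierarchy:
    def test_partof_grounds_s_class_subsumption(self, anatomy):
        p1 = rewrite_axiom(
            RawEQAxiom(
                "P:LV", (("inheres-in", "LeftVentricle"), ("has-quality", "Enlarged"))
            ),
            anatomy,
        )
        s_heart = generate_abstract_class("Heart")
        h = infer_hierarchy([p1, s_heart], anatomy)
        assert h.is_ancestor(s_heart.phenotype_id, "P:LV")

    def test_reflexivity_and_root_reachability(self, anatomy):
        p1 = rewrite_axiom(
            RawEQAxiom("P:H", (("inheres-in", "Heart"), ("has-quality", "Enlarged"))),
            anatomy,
        )
        h = infer_hierarchy([p1], anatomy)
        assert h.is_ancestor("P:H", "P:H")
        assert h.is_ancestor(PHENOTYPE_ROOT, "P:H")

    def test_quality_closure_orders_severities(self, anatomy):
        p1 = rewrite_axiom(
            RawEQAxiom(
                "P:sev", (("inheres-in", "Heart"), ("has-quality", "SeverelyEnlarged"))
            ),
            anatomy,
        )
        p2 = rewrite_axiom(
            RawEQAxiom("P:enl", (("inheres-in", "Heart"), ("has-quality", "Enlarged"))),
            anatomy,
        )
        h = infer_hierarchy([p1, p2], anatomy)
        assert h.is_ancestor("P:enl", "P:sev")
        assert not h.is_ancestor("P:sev", "P:enl")

    def test_unmodified_quality_subsumes_modified(self, anatomy):
        plain = rewrite_axiom(
            RawEQAxiom("P:plain", (("inheres-in", "Heart"), ("has-quality", "Enlarged"))),
            anatomy,
        )
        modified = rewrite_axiom(
            RawEQAxiom(
                "P:mod",
                (
                    ("inheres-in", "Heart"),
                    ("has-quality", "Enlarged"),
                    ("modifier", "Abnormal"),
                ),
            ),
            anatomy,
        )
        h = infer_hierarchy([plain, modified], anatomy)
        assert h.is_ancestor("P:plain", "P:mod")
        assert not h.is_ancestor("P:mod", "P:plain")

    def test_entity_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            EntityOntology(
                classes={"A", "B"},
                isa_edges={("A", "B")},
                partof_edges={("B", "A")},
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_on_random_instances(self, seed):
        ont, defs = random_reasoner_instance(seed)
        h = infer_hierarchy(defs.values(), ont)
        expected = oracle_subsumption_pairs(dict(h.definitions), ont)
        assert h.subsumption_pairs() == expected

    def test_monotone_under_added_entity_edges(self):
        ont, defs = random_reasoner_instance(123, n_entities=20, n_defs=25)
        h_before = infer_hierarchy(defs.values(), ont)
        bigger = EntityOntology(
            classes=set(ont.classes),
            isa_edges=set(ont.isa_edges) | {("E7", "E2")},
            partof_edges=set(ont.partof_edges) | {("E9", "E1")},
        )
        h_after = infer_hierarchy(defs.values(), bigger)
        assert h_before.subsumption_pairs() <= h_after.subsumption_pairs()

    def test_idempotent_rebuild(self):
        ont, defs = random_reasoner_instance(7)
        h1 = infer_hierarchy(defs.values(), ont)
        h2 = infer_hierarchy(h1.definitions.values(), ont)
        assert h1.edges == h2.edges

    def test_concrete_class_reaches_root_through_s_class(self, anatomy):
        axioms = [
            RawEQAxiom(
                "P:LV", (("inheres-in", "LeftVentricle"), ("has-quality", "Enlarged"))
            )
        ]
        h, _ = build_ontology(anatomy, axioms)
        s_classes = [
            c for c in h.ancestors("P:LV")
            if h.definitions[c].is_abstract
        ]
        assert s_classes  # at least the S-class over its own entity


class TestHierarchyIO:
    def test_roundtrip_preserves_closure(self, tmp_path, anatomy):
        ont, defs = random_reasoner_instance(11)
        h = infer_hierarchy(defs.values(), ont)
        write_hierarchy(h, tmp_path)
        h2 = read_hierarchy(tmp_path)
        assert h2.nodes == h.nodes
        assert h2.subsumption_pairs() == h.subsumption_pairs()

    def test_axioms_tsv_reader(self, tmp_path, anatomy):
        path = tmp_path / "axioms.tsv"
        path.write_text(
            "phenotype_id\trelation\tfiller\n"
            "P:1\tinheres-in\tHeart\n"
            "P:1\thas-quality\tEnlarged\n"
            "P:2\thas-part\t_x\n"
            "_x\tinheres-in\tLimb\n"
            "_x\thas-quality\tSmall\n"
        )
        axioms = read_axioms_tsv(path)
        assert [a.phenotype_id for a in axioms] == ["P:1", "P:2"]
        d2 = rewrite_axiom(axioms[1], anatomy)
        assert d2.atoms[0][0].base == "Limb"
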