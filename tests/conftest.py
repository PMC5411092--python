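from __future__ import annotations

import pytest

from phenovar.ontology import PhenotypeHierarchy
from phenovar.similarity import AnnotationCorpus, SimilarityEngine
from phenovar.simulate import (
    SignalModel,
    WorldParams,
    generate_toy_world,
    make_labeled_variants,
)
from phenovar.training import expand_labeled_table, make_training_set, train_model
from phenovar.resources import assign_gene, attach_scores
from dataclasses import replace


@pytest.fixture(scope="session")
def toy_hierarchy() -> PhenotypeHierarchy:
    """The worked toy: A1, A2 ⊑ A; A, B ⊑ Root."""
    return PhenotypeHierarchy(
        nodes={"Root", "A", "B", "A1", "A2"},
        edges={("A1", "A"), ("A2", "A"), ("A", "Root"), ("B", "Root")},
        root="Root",
    )


@pytest.fixture(scope="session")
def toy_corpus() -> AnnotationCorpus:
    """g1:{A1}, g2:{A2}, g3:{B}."""
    return AnnotationCorpus(
        {("g1", "A1", "human"), ("g2", "A2", "human"), ("g3", "B", "human")}
    )


@pytest.fixture(scope="session")
def toy_engine(toy_hierarchy, toy_corpus) -> SimilarityEngine:
    return SimilarityEngine(toy_hierarchy, toy_corpus)


@pytest.fixture(scope="session")
def small_world():
    return generate_toy_world(WorldParams(), seed=42)


def _train_on_world(world, mode: str, seed: int):
    signal = SignalModel("separable")
    labeled, score_tables, maf = make_labeled_variants(world, signal, seed)
    annotated = [
        replace(
            lv,
            variant=assign_gene(attach_scores(lv.variant, score_tables, maf), world.genes),
        )
        for lv in labeled
    ]
    expanded = expand_labeled_table(annotated, world.diseases)
    examples = make_training_set(
        expanded, world.diseases, mode, seed, engine=world.engine(), panel=world.panel
    )
    return train_model(examples, mode, seed), examples


@pytest.fixture(scope="session")
def train_world():
    """A world disjoint from ``small_world`` used only for model fitting."""
    return generate_toy_world(WorldParams(), seed=1000)


@pytest.fixture(scope="session")
def mixed_model(train_world):
    model, _ = _train_on_world(train_world, "mixed", seed=7)
    return model
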