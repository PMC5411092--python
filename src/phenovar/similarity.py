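"""Information content and Resnik/BMA semantic similarity.

Gene–phenotype annotations (human, mouse, zebrafish sources) are propagated
to all hierarchy ancestors (true-path rule); the information content of a
class is the negative natural log of its annotation frequency, IC(c) =
−ln(n_c / N).  Pairwise class similarity is Resnik's measure — the IC of
the most informative common ancestor — and profile-vs-gene similarity uses
the symmetric best-matching-average (BMA) strategy.  Per-profile scores are
normalized to [0, 1] by dividing by the profile's maximum over genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .ontology import PhenotypeHierarchy

SOURCES = ("human", "mouse", "zebrafish")


class SimilarityError(ValueError):
    pass


@dataclass
class AnnotationCorpus:
    """Gene → phenotype-class associations, tagged by source species."""

    #: (gene_id, phenotype_id, source) triples
    associations: set[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for g, p, s in self.associations:
            if s not in SOURCES:
                raise SimilarityError(f"unknown annotation source {s!r}")

    def genes(self, sources: Iterable[str] = SOURCES) -> set[str]:
        src = set(sources)
        return {g for g, _, s in self.associations if s in src}

    def annotations_of(self, gene: str, sources: Iterable[str] = SOURCES) -> set[str]:
        src = set(sources)
        return {p for g, p, s in self.associations if g == gene and s in src}

    def restricted(self, sources: Iterable[str]) -> "AnnotationCorpus":
        src = set(sources)
        return AnnotationCorpus({t for t in self.associations if t[2] in src})


@dataclass(frozen=True)
class PhenotypeProfile:
    """A patient (or disease) phenotype profile: a non-empty set of
    phenotype class IDs plus an optional mode of inheritance."""

    phenotypes: frozenset[str]
    moi: str | None = None

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise SimilarityError("empty phenotype profile")

    @staticmethod
    def of(phenotypes: Iterable[str], moi: str | None = None) -> "PhenotypeProfile":
        return PhenotypeProfile(frozenset(phenotypes), moi)


def compute_ic(
    corpus: AnnotationCorpus,
    hierarchy: PhenotypeHierarchy,
    sources: Iterable[str] = SOURCES,
) -> dict[str, float]:
    """Annotation-frequency information content per phenotype class.

    Annotations propagate to all ancestors; IC(c) = −ln(n_c / N) with N the
    total number of annotated genes.  Classes no gene is annotated to get
    the corpus minimum frequency 1/N (finite maximum IC) so Resnik values
    never become infinite.
    """
    src = set(sources)
    gene_sets: dict[str, set[str]] = {}
    for g, p, s in corpus.associations:
        if s in src:
            if not hierarchy.has_class(p):
                raise SimilarityError(f"annotation to unknown class {p!r}")
            gene_sets.setdefault(g, set()).add(p)
    n_total = len(gene_sets)
    if n_total == 0:
        raise SimilarityError("empty annotation corpus")
    counts: dict[str, int] = {c: 0 for c in hierarchy.nodes}
    for g, annots in gene_sets.items():
        covered: set[str] = set()
        for p in annots:
            covered |= hierarchy.ancestors(p)
        for c in covered:
            counts[c] += 1
    ic: dict[str, float] = {}
    for c, n_c in counts.items():
        ic[c] = -math.log(max(n_c, 1) / n_total)
    ic[hierarchy.root] = 0.0
    return ic


class SimilarityEngine:
    """Resnik/BMA similarity search against a gene–phenotype corpus.

    Parameters
    ----------
    hierarchy:
        Inferred phenotype subsumption hierarchy.
    corpus:
        Full annotation corpus; ``sources`` restricts it to a configuration
        (human-only, model-organism-only, or both).
    """

    def __init__(
        self,
        hierarchy: PhenotypeHierarchy,
        corpus: AnnotationCorpus,
        sources: Iterable[str] = SOURCES,
    ) -> None:
        self.hierarchy = hierarchy
        self.sources = tuple(sources)
        self.corpus = corpus.restricted(self.sources)
        self.ic = compute_ic(self.corpus, hierarchy)
        self._gene_annotations = {
            g: frozenset(self.corpus.annotations_of(g)) for g in self.corpus.genes()
        }
        self._resnik_cache: dict[tuple[str, str], float] = {}

    def resnik(self, c1: str, c2: str) -> float:
        """IC of the most informative common ancestor of ``c1`` and ``c2``
        (each class counts among its own ancestors)."""
        if not self.hierarchy.has_class(c1):
            raise SimilarityError(f"unknown phenotype class {c1!r}")
        if not self.hierarchy.has_class(c2):
            raise SimilarityError(f"unknown phenotype class {c2!r}")
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        hit = self._resnik_cache.get(key)
        if hit is not None:
            return hit
        common = self.hierarchy.ancestors(c1) & self.hierarchy.ancestors(c2)
        val = max(self.ic[c] for c in common)
        self._resnik_cache[key] = val
        return val

    def bma(self, set1: Iterable[str], set2: Iterable[str]) -> float:
        """Symmetric best-matching-average of two phenotype class sets."""
        s1, s2 = list(set1), list(set2)
        if not s1 or not s2:
            raise SimilarityError("BMA of an empty phenotype set")
        fwd = sum(max(self.resnik(x, y) for y in s2) for x in s1) / len(s1)
        rev = sum(max(self.resnik(x, y) for x in s1) for y in s2) / len(s2)
        return 0.5 * (fwd + rev)

    def gene_scores(self, profile: PhenotypeProfile) -> dict[str, float]:
        """Raw BMA similarity between ``profile`` and every gene in the
        active corpus configuration."""
        return {
            g: self.bma(profile.phenotypes, annots)
            for g, annots in sorted(self._gene_annotations.items())
        }

    def normalized_gene_scores(self, profile: PhenotypeProfile) -> dict[str, float]:
        return normalize_profile_scores(self.gene_scores(profile))


def normalize_profile_scores(raw: Mapping[str, float]) -> dict[str, float]:
    """Scale one profile's gene scores to [0, 1] by the profile maximum;
    an all-zero profile maps to all zeros."""
    if not raw:
        raise SimilarityError("no gene scores to normalize")
    top = max(raw.values())
    if top <= 0:
        return {g: 0.0 for g in raw}
    return {g: v / top for g, v in raw.items()}


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------

CORPUS_COLUMNS = ["gene_id", "phenotype_id", "source"]


def read_corpus(path) -> AnnotationCorpus:
    """Read gene–phenotype associations from a 3-column TSV."""
    import csv

    assoc: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != CORPUS_COLUMNS:
            raise SimilarityError(f"unexpected corpus columns: {header}")
        for row in reader:
            if row:
                assoc.add((row[0], row[1], row[2]))
    return AnnotationCorpus(assoc)


def write_corpus(corpus: AnnotationCorpus, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CORPUS_COLUMNS) + "\n")
        for g, p, s in sorted(corpus.associations):
            fh.write(f"{g}\t{p}\t{s}\n")


def write_gene_scores(raw: Mapping[str, float], normalized: Mapping[str, float], path) -> None:
    """Per-patient gene similarity table (gene_id, raw, normalized)."""
    with open(path, "w") as fh:
        fh.write("gene_id\traw\tnormalized\n")
        for g in sorted(raw):
            fh.write(f"{g}\t{raw[g]:.10g}\t{normalized[g]:.10g}\n")
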