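"""The 60-feature representation of a (variant, patient-profile) pair.

Order (fixed; this is the serialization and model signature order):

  0-2    score_1..score_3   — three pathogenicity-predictor scores (NaN if
                              the predictor did not score the variant)
  3      zygosity           — het=0, hom=1
  4      moi                — Dominant=0, Recessive=1, X-linked=2, Other=3
  5-58   toplevel_01..54    — binary flags: does any profile class fall
                              under the k-th high-level panel phenotype
  59     similarity         — normalized Resnik/BMA similarity between the
                              profile and the variant's gene, in [0, 1]

3 + 1 + 1 + 54 + 1 = 60.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .ontology import PhenotypeHierarchy
from .resources import HET, HOM, MOI_VALUES, UNCALLED, VariantRecord
from .similarity import PhenotypeProfile

PANEL_SIZE = 54

ZYGOSITY_CODES = {HET: 0.0, HOM: 1.0}
MOI_CODES = {m: float(i) for i, m in enumerate(MOI_VALUES)}

FEATURE_NAMES: tuple[str, ...] = (
    "score_1",
    "score_2",
    "score_3",
    "zygosity",
    "moi",
    *(f"toplevel_{k:02d}" for k in range(1, PANEL_SIZE + 1)),
    "similarity",
)

N_FEATURES = len(FEATURE_NAMES)  # 60

#: Feature kinds drive imputation: numeric -> median, categorical -> mode.
CATEGORICAL_FEATURES = frozenset(
    ["zygosity", "moi", *(f"toplevel_{k:02d}" for k in range(1, PANEL_SIZE + 1))]
)


class FeatureError(ValueError):
    pass


def derive_panel(hierarchy: PhenotypeHierarchy, size: int = PANEL_SIZE) -> list[str]:
    """Derive a high-level phenotype panel from a hierarchy.

    Takes classes in breadth-first order from the root's children (the
    analogue of the upper-level classes of the human/mouse phenotype
    vocabularies); small hierarchies are padded with the root so the panel
    always has exactly ``size`` entries.
    """
    panel: list[str] = []
    seen = {hierarchy.root}
    frontier = hierarchy.children_of(hierarchy.root)
    while frontier and len(panel) < size:
        nxt: list[str] = []
        for c in frontier:
            if c not in seen:
                seen.add(c)
                panel.append(c)
                if len(panel) == size:
                    break
                nxt.extend(hierarchy.children_of(c))
        frontier = sorted(set(nxt) - seen)
    while len(panel) < size:
        panel.append(hierarchy.root)
    return panel


def toplevel_phenotype_flags(
    profile: PhenotypeProfile,
    hierarchy: PhenotypeHierarchy,
    panel: Sequence[str],
) -> np.ndarray:
    """Binary vector: flag k is 1 iff any profile class is subsumed by
    (i.e. has among its ancestors, reflexively) the k-th panel class."""
    if len(panel) != PANEL_SIZE:
        raise FeatureError(f"panel must have {PANEL_SIZE} classes, got {len(panel)}")
    for c in panel:
        if not hierarchy.has_class(c):
            raise FeatureError(f"panel class {c!r} not in hierarchy")
    ancestors: set[str] = set()
    for p in profile.phenotypes:
        ancestors |= hierarchy.ancestors(p)
    return np.array([1.0 if c in ancestors else 0.0 for c in panel])


def build_features(
    v: VariantRecord,
    profile: PhenotypeProfile,
    sim: Mapping[str, float],
    hierarchy: PhenotypeHierarchy,
    panel: Sequence[str],
) -> np.ndarray:
    """Assemble the 60-feature vector for one variant against one profile.

    ``sim`` is the profile's normalized gene-similarity table; a variant
    in an unassigned or unannotated gene gets similarity 0.  Missing
    pathogenicity scores become NaN for downstream imputation.  Uncalled
    genotypes are rejected — they must be filtered out upstream.
    """
    if v.genotype == UNCALLED:
        raise FeatureError(f"uncalled genotype for {v.key}; filter first")
    moi = profile.moi if profile.moi in MOI_VALUES else "Other"
    similarity = sim.get(v.gene, 0.0) if v.gene is not None else 0.0
    scores = [np.nan if s is None else float(s) for s in v.scores]
    flags = toplevel_phenotype_flags(profile, hierarchy, panel)
    vec = np.empty(N_FEATURES)
    vec[0:3] = scores
    vec[3] = ZYGOSITY_CODES[v.genotype]
    vec[4] = MOI_CODES[moi]
    vec[5 : 5 + PANEL_SIZE] = flags
    vec[59] = similarity
    return vec


def write_feature_matrix(X: np.ndarray, path) -> None:
    """Write a feature matrix as TSV with the documented header order."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(FEATURE_NAMES)
        for row in np.atleast_2d(X):
            w.writerow([f"{x:.10g}" for x in row])


def read_feature_matrix(path) -> np.ndarray:
    import csv

    with open(path) as fh:
        r = csv.reader(fh, delimiter="\t")
        header = tuple(next(r))
        if header != FEATURE_NAMES:
            raise FeatureError("feature header does not match documented order")
        return np.array([[float(x) for x in row] for row in r])
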