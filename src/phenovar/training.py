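"""Training-set construction and the random-forest causative classifier.

Positives are pathogenic variants paired with their own disease's
phenotype profile; two kinds of negatives exist: *pathogenic
non-causative* (the same pathogenic variants paired with a different,
randomly chosen disease's phenotypes) and *benign non-causative* (benign
variants paired with a random disease).  Three negative-sampling regimes
produce three models:

``pathogenic``
    only pathogenic non-causative negatives — positives and negatives have
    indistinguishable pathogenicity scores, so the model is driven by the
    phenotype-similarity feature;
``benign``
    only benign negatives — separable by pathogenicity scores alone, so
    the model under-emphasizes similarity;
``mixed``
    a 50/50 blend (the larger pool subsampled), balancing both signals.

The classifier is a random forest (100 trees, unlimited depth, 6 candidate
features per split) whose probability estimate is the ranking score.
Missing feature values are imputed by label-conditional median/mode at fit
time; pooled values are stored on the model and applied at prediction
time, when labels are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import CATEGORICAL_FEATURES, FEATURE_NAMES, N_FEATURES, build_features
from .resources import (
    HET,
    HOM,
    Disease,
    DiseaseTable,
    LabeledVariant,
    VariantRecord,
)
from .similarity import PhenotypeProfile, SimilarityEngine

NEGATIVE_MODES = ("pathogenic", "benign", "mixed")

PROVENANCE_POSITIVE = "pathogenic-causative"
PROVENANCE_PATHOGENIC_NEG = "pathogenic-non-causative"
PROVENANCE_BENIGN_NEG = "benign-non-causative"


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledExample:
    features: np.ndarray
    label: int  # 1 = causative, 0 = non-causative
    provenance: str

    def __post_init__(self) -> None:
        if (self.label == 1) != (self.provenance == PROVENANCE_POSITIVE):
            raise TrainingError("label/provenance mismatch")


def expand_genotypes(
    variant: VariantRecord, moi: str
) -> list[VariantRecord]:
    """Candidate disease genotypes for a variant given the disease's mode
    of inheritance: recessive diseases yield a single homozygote, all
    other modes a heterozygote and a homozygote."""
    if moi == "Recessive":
        return [replace(variant, genotype=HOM)]
    return [replace(variant, genotype=HET), replace(variant, genotype=HOM)]


def expand_labeled_table(
    labeled: Sequence[LabeledVariant], diseases: DiseaseTable
) -> list[LabeledVariant]:
    """Apply genotype expansion to every row of a labeled table.

    Pathogenic rows expand by their own disease's mode of inheritance;
    benign rows (no disease) expand as het + hom.  Pathogenic rows whose
    disease has no phenotype annotations are dropped (no profile can be
    built for them)."""
    out: list[LabeledVariant] = []
    for lv in labeled:
        if lv.label == "pathogenic":
            disease = diseases.get(lv.disease_id)
            if disease is None or not disease.phenotypes:
                continue
            moi = disease.moi
        else:
            moi = "Other"
        for v in expand_genotypes(lv.variant, moi):
            out.append(replace(lv, variant=v))
    return out


def _profiled_features(
    variant: VariantRecord,
    disease: Disease,
    engine: SimilarityEngine,
    panel: Sequence[str],
    sim_cache: dict[str, Mapping[str, float]],
) -> np.ndarray:
    sim = sim_cache.get(disease.disease_id)
    if sim is None:
        sim = engine.normalized_gene_scores(PhenotypeProfile(disease.phenotypes))
        sim_cache[disease.disease_id] = sim
    profile = PhenotypeProfile(disease.phenotypes, moi=disease.moi)
    return build_features(variant, profile, sim, engine.hierarchy, panel)


def make_training_set(
    labeled: Sequence[LabeledVariant],
    diseases: DiseaseTable,
    mode: str,
    seed: int,
    *,
    engine: SimilarityEngine,
    panel: Sequence[str],
) -> list[LabeledExample]:
    """Build labeled feature vectors under one negative-sampling regime.

    Every (genotype-expanded) pathogenic row yields one positive paired
    with its own disease and one pathogenic non-causative negative paired
    with a uniformly random *different* disease; every benign row yields
    one benign negative paired with a random disease.  ``mode`` selects
    the negative composition; in ``mixed`` the larger negative pool is
    subsampled to the size of the smaller (seeded).
    """
    if mode not in NEGATIVE_MODES:
        raise TrainingError(f"unknown negative mode {mode!r}")
    usable = {d: dz for d, dz in diseases.items() if dz.phenotypes}
    if len(usable) < 2:
        raise TrainingError("need >= 2 phenotype-annotated diseases to mismatch")
    rng = np.random.default_rng(seed)
    ids = sorted(usable)
    sim_cache: dict[str, Mapping[str, float]] = {}

    positives: list[LabeledExample] = []
    pathogenic_negs: list[LabeledExample] = []
    benign_negs: list[LabeledExample] = []
    for lv in labeled:
        if lv.label == "pathogenic":
            disease = usable.get(lv.disease_id)
            if disease is None:
                continue
            x = _profiled_features(lv.variant, disease, engine, panel, sim_cache)
            positives.append(LabeledExample(x, 1, PROVENANCE_POSITIVE))
            if mode in ("pathogenic", "mixed"):
                others = [d for d in ids if d != lv.disease_id]
                wrong = usable[others[rng.integers(len(others))]]
                xn = _profiled_features(lv.variant, wrong, engine, panel, sim_cache)
                pathogenic_negs.append(
                    LabeledExample(xn, 0, PROVENANCE_PATHOGENIC_NEG)
                )
        else:
            if mode in ("benign", "mixed"):
                dz = usable[ids[rng.integers(len(ids))]]
                xb = _profiled_features(lv.variant, dz, engine, panel, sim_cache)
                benign_negs.append(LabeledExample(xb, 0, PROVENANCE_BENIGN_NEG))
    if mode == "pathogenic":
        negatives = pathogenic_negs
    elif mode == "benign":
        negatives = benign_negs
    else:
        n = min(len(pathogenic_negs), len(benign_negs))
        if n == 0:
            raise TrainingError("mixed mode needs both negative pools non-empty")
        pn = [pathogenic_negs[i] for i in sorted(rng.choice(len(pathogenic_negs), n, replace=False))]
        bn = [benign_negs[i] for i in sorted(rng.choice(len(benign_negs), n, replace=False))]
        negatives = pn + bn
    return positives + negatives


def examples_to_arrays(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([e.features for e in examples])
    y = np.array([e.label for e in examples])
    return X, y


def split_by_variant(
    labeled: Sequence[LabeledVariant], test_fraction: float, seed: int
) -> tuple[list[LabeledVariant], list[LabeledVariant]]:
    """Seeded train/test split at the *variant* level: all rows of one
    variant key land on the same side, so no test variant leaks into
    training."""
    keys = sorted({lv.variant.key for lv in labeled})
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_test = max(1, int(round(test_fraction * len(keys))))
    test_keys = set(keys[:n_test])
    train = [lv for lv in labeled if lv.variant.key not in test_keys]
    test = [lv for lv in labeled if lv.variant.key in test_keys]
    return train, test


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class LabelConditionalImputer(TransformerMixin, BaseEstimator):
    """Impute missing values by label-conditional median (numeric) or mode
    (categorical) at fit time; pooled values are kept for unlabeled
    transform calls at prediction time.

    Parameters
    ----------
    categorical_mask : sequence of bool of length n_features, optional
        Which columns are categorical; defaults to the documented feature
        layout when the input has the canonical 60 columns.
    """

    def __init__(self, categorical_mask: Sequence[bool] | None = None):
        self.categorical_mask = categorical_mask

    def _mask(self, n: int) -> np.ndarray:
        if self.categorical_mask is not None:
            return np.asarray(self.categorical_mask, dtype=bool)
        if n == N_FEATURES:
            return np.array([f in CATEGORICAL_FEATURES for f in FEATURE_NAMES])
        return np.zeros(n, dtype=bool)

    @staticmethod
    def _fill(col: np.ndarray, categorical: bool) -> float:
        vals = col[~np.isnan(col)]
        if vals.size == 0:
            return np.nan
        if categorical:
            uniq, counts = np.unique(vals, return_counts=True)
            return float(uniq[np.argmax(counts)])
        return float(np.median(vals))

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        mask = self._mask(X.shape[1])
        fully_missing = np.all(np.isnan(X), axis=0)
        if fully_missing.any():
            idx = int(np.flatnonzero(fully_missing)[0])
            name = FEATURE_NAMES[idx] if X.shape[1] == N_FEATURES else f"column {idx}"
            raise TrainingError(f"feature {name} is missing in every example")
        self.pooled_fill_ = np.array(
            [self._fill(X[:, j], mask[j]) for j in range(X.shape[1])]
        )
        self.label_fill_ = {}
        if y is not None:
            y = np.asarray(y)
            for label in np.unique(y):
                sub = X[y == label]
                self.label_fill_[label] = np.array(
                    [self._fill(sub[:, j], mask[j]) for j in range(X.shape[1])]
                )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, y=None):
        check_is_fitted(self, "pooled_fill_")
        X = np.asarray(X, dtype=float).copy()
        if y is None:
            fills = np.broadcast_to(self.pooled_fill_, X.shape)
            np.putmask(X, np.isnan(X), fills)
            return X
        y = np.asarray(y)
        for label in np.unique(y):
            rows = y == label
            fill = self.label_fill_.get(label, self.pooled_fill_)
            fill = np.where(np.isnan(fill), self.pooled_fill_, fill)
            sub = X[rows]
            np.putmask(sub, np.isnan(sub), np.broadcast_to(fill, sub.shape))
            X[rows] = sub
        return X


class CausativeVariantClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest classifier of causative vs non-causative variants.

    A thin, sklearn-compatible estimator: 100 trees, unlimited depth, 6
    candidate features per split, probability output used as the ranking
    score.  Handles missing values through a
    :class:`LabelConditionalImputer` fitted alongside the forest.

    Parameters
    ----------
    n_trees : int, default 100
    max_features : int, default 6
        Candidate features considered at each split.
    negative_mode : {"pathogenic", "benign", "mixed"}, default "mixed"
        Recorded provenance of the training regime (does not change
        fitting; the regime is realized by :func:`make_training_set`).
    random_state : int, default 0
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_features: int = 6,
        negative_mode: str = "mixed",
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.negative_mode = negative_mode
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise TrainingError("training data contains a single label")
        if self.negative_mode not in NEGATIVE_MODES:
            raise TrainingError(f"unknown negative mode {self.negative_mode!r}")
        self.imputer_ = LabelConditionalImputer().fit(X, y)
        Xi = self.imputer_.transform(X, y)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=None,
            max_features=min(self.max_features, X.shape[1]),
            random_state=self.random_state,
        ).fit(Xi, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        if X.shape[1] == N_FEATURES:
            self.feature_names_in_ = np.array(FEATURE_NAMES, dtype=object)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise TrainingError(
                f"feature signature mismatch: model expects {self.n_features_in_} "
                f"features, got {X.shape[1]}"
            )
        return self.forest_.predict_proba(self.imputer_.transform(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def causative_probability(self, X) -> np.ndarray:
        """P(causative) per row — the variant ranking score."""
        proba = self.predict_proba(X)
        col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, col]


def train_model(
    examples: Sequence[LabeledExample], mode: str, seed: int
) -> CausativeVariantClassifier:
    """Fit the causative classifier on constructed examples."""
    X, y = examples_to_arrays(examples)
    return CausativeVariantClassifier(
        negative_mode=mode, random_state=seed
    ).fit(X, y)


def crossvalidate(
    examples: Sequence[LabeledExample], k: int, seed: int
) -> dict:
    """Stratified k-fold cross-validation; per-fold and mean ROC AUC and
    F-measure."""
    if k < 2:
        raise TrainingError("k must be >= 2")
    X, y = examples_to_arrays(examples)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise TrainingError(
            f"class too small to stratify: {counts.min()} examples for {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, f1s = [], []
    pooled_scores = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        clf = CausativeVariantClassifier(random_state=seed).fit(X[train_idx], y[train_idx])
        scores = clf.causative_probability(X[test_idx])
        pooled_scores[test_idx] = scores
        aucs.append(float(roc_auc_score(y[test_idx], scores)))
        f1s.append(float(f1_score(y[test_idx], (scores >= 0.5).astype(int))))
    return {
        "fold_auc": aucs,
        "fold_f1": f1s,
        "mean_auc": float(np.mean(aucs)),
        "mean_f1": float(np.mean(f1s)),
        "pooled_auc": float(roc_auc_score(y, pooled_scores)),
        "pooled_f1": float(f1_score(y, (pooled_scores >= 0.5).astype(int))),
    }


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def save_model(model: CausativeVariantClassifier, path) -> None:
    """Serialize a fitted model with its feature signature."""
    import joblib

    check_is_fitted(model, "forest_")
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": list(FEATURE_NAMES),
            "model": model,
        },
        path,
    )


def load_model(path) -> CausativeVariantClassifier:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise TrainingError(f"unsupported model format in {path}")
    if payload.get("feature_names") != list(FEATURE_NAMES):
        raise TrainingError("model feature signature does not match this build")
    return payload["model"]
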