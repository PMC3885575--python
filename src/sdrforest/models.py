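"""Per-enzyme binary predictors and the forest-derived SDR procedure.

``EnzymeFunctionForest`` is a scikit-learn-style classifier: a 500-tree
random forest with ⌊√n⌋ candidate attributes per split, out-of-bag error and
per-attribute importances.  ``TopHitBaseline`` is the baseline: a single
entropy-criterion decision tree on the top-hit bit score alone.  From a
fitted forest the top 3·⌊√n⌋ importance-ranked attributes are the "highly
contributing attributes"; the representative positions behind them (skipping
the blast and full-length attributes) are the forest-derived
specificity-determining residues (rf-SDRs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .annotation import PSSM, SiteSets
from .io import ProfileMatrix, ScoringMatrix, SequenceRecord, blosum62
from .scoring import AttributeSchema, AttributeVector, build_attribute_vector

__all__ = [
    "EnzymeFunctionForest",
    "TopHitBaseline",
    "ImportanceRanking",
    "RfSdr",
    "RfSdrSet",
    "EnzymeModelSpec",
    "EnzymePredictor",
    "train_forest",
    "train_simple",
    "rank_importance",
    "extract_rf_sdrs",
]

N_TREES = 500
SDR_MULTIPLIER = 3


class EnzymeFunctionForest(ClassifierMixin, BaseEstimator):
    """Random-forest binary predictor of one enzyme's four-digit EC.

    Parameters
    ----------
    n_estimators : int, default 500
        Trees in the forest.
    mtry : int or None
        Candidate attributes per split; None means ⌊√n⌋ where n is the
        number of input attributes.
    importance : {"impurity", "permutation"}
        Attribute-importance measure; mean decrease in impurity by default.
    random_state : int or None
        Seed; (data, seed) fully determine the model.

    Attributes
    ----------
    forest_ : fitted RandomForestClassifier
    oob_error_ : float, out-of-bag error estimate
    importances_ : ndarray (n,), per-attribute importance scores
    mtry_ : int, realized number of split candidates
    """

    def __init__(
        self,
        n_estimators: int = N_TREES,
        mtry: Optional[int] = None,
        importance: str = "impurity",
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.mtry = mtry
        self.importance = importance
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        n = X.shape[1]
        if n == 0:
            raise ValueError("no input attributes")
        self.mtry_ = self.mtry if self.mtry is not None else max(1, int(math.isqrt(n)))
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.mtry_,
            criterion="gini",
            oob_score=True,
            bootstrap=True,
            n_jobs=1,
            random_state=self.random_state,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = n
        self.oob_error_ = 1.0 - float(self.forest_.oob_score_)
        if self.importance == "impurity":
            self.importances_ = self.forest_.feature_importances_.copy()
        elif self.importance == "permutation":
            perm = permutation_importance(
                self.forest_, X, y, n_repeats=10, random_state=self.random_state
            )
            self.importances_ = perm.importances_mean
        else:
            raise ValueError(f"unknown importance measure {self.importance!r}")
        return self

    def predict(self, X):
        return (self.predict_vote_fraction(X) > 0.5).astype(int)

    def predict_vote_fraction(self, X):
        """Fraction of trees voting positive; label positive iff > 0.5
        (exact ties are negative)."""
        check_is_fitted(self, "forest_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"attribute count {X.shape[1]} does not match the model schema ({self.n_features_in_})"
            )
        proba = self.forest_.predict_proba(X)
        pos_col = int(np.flatnonzero(self.forest_.classes_ == 1)[0])
        return proba[:, pos_col]

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(check_array(X))


class TopHitBaseline(ClassifierMixin, BaseEstimator):
    """Single decision tree on the top-hit bit score (the "simple model").

    An entropy-criterion tree with a minimum leaf of two samples; on a
    one-attribute problem this reduces to the information-gain-optimal
    threshold structure of classic C4.5.
    """

    def __init__(self, min_samples_leaf: int = 2, random_state: Optional[int] = None):
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        self.tree_model_ = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        )
        self.tree_model_.fit(X, y)
        self.classes_ = self.tree_model_.classes_
        self.n_features_in_ = X.shape[1]
        tree = self.tree_model_.tree_
        self.thresholds_ = sorted(
            float(t) for t, f in zip(tree.threshold, tree.feature) if f >= 0
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_model_")
        return self.tree_model_.predict(check_array(X))


@dataclass
class ImportanceRanking:
    """Attributes sorted by importance (descending; ties by schema index).

    ``prefix`` holds the indices of the highly contributing attributes:
    the top min(3·⌊√n⌋, n).
    """

    order: list[int]
    importances: np.ndarray
    prefix_length: int

    @property
    def prefix(self) -> list[int]:
        return self.order[: self.prefix_length]


def rank_importance(model: EnzymeFunctionForest, multiplier: int = SDR_MULTIPLIER) -> ImportanceRanking:
    """Rank a fitted forest's attributes; prefix length min(3·⌊√n⌋, n)."""
    check_is_fitted(model, "importances_")
    imp = np.asarray(model.importances_)
    n = imp.size
    order = sorted(range(n), key=lambda i: (-imp[i], i))
    prefix_length = min(multiplier * int(math.isqrt(n)), n)
    return ImportanceRanking(order=order, importances=imp, prefix_length=prefix_length)


@dataclass
class RfSdr:
    """One forest-derived SDR: a representative position with provenance."""

    position: int  # 0-based
    category: str  # "asr" | "lbr" | "csr"
    matrices: set[str] = field(default_factory=set)
    best_rank: int = 0  # rank (0-based) of its best attribute in the ranking


@dataclass
class RfSdrSet:
    """Deduplicated rf-SDR positions of one enzyme."""

    sdrs: dict[int, RfSdr] = field(default_factory=dict)

    @property
    def positions(self) -> set[int]:
        return set(self.sdrs)

    def __len__(self) -> int:
        return len(self.sdrs)


def extract_rf_sdrs(
    ranking: ImportanceRanking,
    schema: AttributeSchema,
    sites: SiteSets,
) -> RfSdrSet:
    """Positions behind the highly contributing attributes.

    Walks the ranking prefix, skips blast and full-length attributes, and
    collects each position attribute's representative position, tagged with
    its site category and the scoring schemes under which it was selected.
    """
    out = RfSdrSet()
    for rank, idx in enumerate(ranking.prefix):
        desc = schema.descriptors[idx]
        if desc.kind != "position":
            continue
        pos = desc.position
        if pos not in sites.all_positions:
            raise ValueError(f"schema position {pos + 1} missing from the enzyme's site sets")
        if pos in out.sdrs:
            out.sdrs[pos].matrices.add(desc.matrix)
        else:
            out.sdrs[pos] = RfSdr(
                position=pos,
                category=sites.category_of(pos),
                matrices={desc.matrix},
                best_rank=rank,
            )
    return out


@dataclass
class EnzymeModelSpec:
    """Everything needed to turn a query into an attribute vector for one enzyme."""

    ec: str
    representative: SequenceRecord
    sites: SiteSets
    schema: AttributeSchema
    pssm: PSSM
    training_positives: list[SequenceRecord]
    matrix: ScoringMatrix = field(default_factory=blosum62)
    esst: Optional[ProfileMatrix] = None

    def scorers(self) -> dict[str, ScoringMatrix | ProfileMatrix]:
        out: dict[str, ScoringMatrix | ProfileMatrix] = {
            "blosum62": self.matrix,
            "pssm": self.pssm.profile,
        }
        if self.esst is not None:
            out["esst"] = self.esst
        return out


@dataclass
class EnzymePredictor:
    """A trained enzyme predictor: spec + forest + baseline + derived SDRs."""

    spec: EnzymeModelSpec
    forest: EnzymeFunctionForest
    simple: TopHitBaseline
    ranking: ImportanceRanking
    rf_sdrs: RfSdrSet

    def attribute_vector(self, query: SequenceRecord, mode: str = "prediction", **kw) -> AttributeVector:
        return build_attribute_vector(query, self.spec, mode=mode, **kw)

    def predict_query(self, query: SequenceRecord, **kw) -> tuple[int, float]:
        vec = self.attribute_vector(query, **kw)
        X = vec.values[None, :]
        frac = float(self.forest.predict_vote_fraction(X)[0])
        return int(frac > 0.5), frac


def train_forest(
    vectors: Sequence[AttributeVector] | np.ndarray,
    labels: Sequence[int],
    n_estimators: int = N_TREES,
    mtry: Optional[int] = None,
    seed: Optional[int] = None,
    importance: str = "impurity",
) -> EnzymeFunctionForest:
    X = _as_matrix(vectors)
    model = EnzymeFunctionForest(
        n_estimators=n_estimators, mtry=mtry, importance=importance, random_state=seed
    )
    return model.fit(X, np.asarray(labels))


def train_simple(
    blast_scores: Sequence[float],
    labels: Sequence[int],
    seed: Optional[int] = None,
) -> TopHitBaseline:
    X = np.asarray(blast_scores, dtype=float).reshape(-1, 1)
    return TopHitBaseline(random_state=seed).fit(X, np.asarray(labels))


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return vectors
    return np.vstack([v.values for v in vectors])
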