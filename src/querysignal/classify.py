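"""Antecedent-query feature matrices and cross-validated AUC evaluation.

Each user is represented by the number of times they queried for each
symptom and each medical condition strictly before their index date (the
first CRQ for cohort members; for comparison users a pseudo-index date
drawn from the cohort's t0 distribution, so both classes see comparable
observation windows).  A predictive model — ordinary least squares on the
binary label, ranked as a score, or a random forest with 50 trees — is
evaluated with stratified 10-fold cross-validation, reporting the area
under the ROC curve on held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from querysignal.cohort import CohortMember
from querysignal.lexicon import Lexicon, match_concept_ids_bulk
from querysignal.signal import _user_groups

__all__ = ["FeatureMatrix", "AucResult", "build_feature_matrix", "evaluate_auc"]

MODEL_SPECS = ("linear_regression", "random_forest")


@dataclass
class FeatureMatrix:
    """Per-user antecedent concept counts with binary labels.

    Columns are the symptom concepts in lexicographic order followed by the
    condition concepts in lexicographic order; entries are non-negative
    query counts before the user's (pseudo-)index date.  Row order is the
    input order: target users first, then comparison users.
    """

    X: np.ndarray
    y: np.ndarray
    user_ids: list[str]
    columns: list[str]
    index_dates: list[pd.Timestamp]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "user_id", self.user_ids)
        df["label"] = self.y
        return df


def build_feature_matrix(
    target_members: list[CohortMember],
    comparison_user_ids: list[str],
    records: pd.DataFrame,
    symptom_lexicon: Lexicon,
    condition_lexicon: Lexicon,
    seed: int = 0,
) -> FeatureMatrix:
    """Count pre-index symptom/condition queries per user.

    Comparison users receive pseudo-index dates sampled uniformly (with the
    given seed) from the target users' t0 values, anchoring them to the
    same calendar distribution.  Users with no pre-index queries keep an
    all-zero row.
    """
    if not target_members and comparison_user_ids:
        raise ValueError("cannot anchor comparison users without target members")
    sym_cols = symptom_lexicon.concept_ids
    cond_cols = condition_lexicon.concept_ids
    columns = sym_cols + cond_cols
    col_of = {c: j for j, c in enumerate(sym_cols)}
    cond_off = len(sym_cols)
    for j, c in enumerate(cond_cols):
        col_of[("cond", c)] = cond_off + j

    rng = np.random.default_rng(seed)
    t0s = [m.t0 for m in target_members]
    pseudo = (
        [t0s[i] for i in rng.integers(0, len(t0s), size=len(comparison_user_ids))]
        if comparison_user_ids
        else []
    )

    user_ids = [m.user_id for m in target_members] + list(comparison_user_ids)
    index_dates = t0s + pseudo
    y = np.concatenate(
        [np.ones(len(target_members), dtype=np.int64), np.zeros(len(comparison_user_ids), dtype=np.int64)]
    ) if user_ids else np.zeros(0, dtype=np.int64)

    X = np.zeros((len(user_ids), len(columns)), dtype=np.int64)
    groups = _user_groups(records)
    sym_cache: dict[str, frozenset[str]] = {}
    cond_cache: dict[str, frozenset[str]] = {}
    for row, (uid, t_idx) in enumerate(zip(user_ids, index_dates)):
        sub = groups.get(uid)
        if sub is None:
            continue
        pre = sub.loc[(sub["timestamp"] < t_idx).to_numpy(), "norm_text"]
        if pre.empty:
            continue
        for s in match_concept_ids_bulk(pre, symptom_lexicon, cache=sym_cache):
            for cid in s:
                X[row, col_of[cid]] += 1
        for s in match_concept_ids_bulk(pre, condition_lexicon, cache=cond_cache):
            for cid in s:
                X[row, col_of[("cond", cid)]] += 1
    return FeatureMatrix(X=X, y=y, user_ids=user_ids, columns=columns, index_dates=index_dates)


@dataclass
class AucResult:
    """Cross-validated discrimination performance."""

    model_spec: str
    folds: int
    seed: int
    fold_aucs: list[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def evaluate_auc(
    matrix: FeatureMatrix,
    model_spec: str = "random_forest",
    n_trees: int = 50,
    folds: int = 10,
    seed: int = 0,
) -> AucResult:
    """Stratified k-fold cross-validated AUC for one model specification.

    Rows are sorted by user id before folding so the fold assignment is a
    deterministic function of (user set, seed), independent of input order.
    "linear_regression" fits ordinary least squares on the 0/1 label and
    ranks its continuous prediction; "random_forest" uses the positive-class
    probability of a forest with ``n_trees`` trees.
    """
    if model_spec not in MODEL_SPECS:
        raise ValueError(f"model_spec must be one of {MODEL_SPECS}")
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to evaluate discrimination")

    order = np.argsort(np.asarray(matrix.user_ids, dtype=object))
    X = matrix.X[order]
    yy = y[order]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    for train_idx, test_idx in skf.split(X, yy):
        if model_spec == "linear_regression":
            model = LinearRegression()
            model.fit(X[train_idx], yy[train_idx])
            scores = model.predict(X[test_idx])
        else:
            model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
            model.fit(X[train_idx], yy[train_idx])
            scores = model.predict_proba(X[test_idx])[:, 1]
        fold_aucs.append(float(roc_auc_score(yy[test_idx], scores)))
    return AucResult(model_spec=model_spec, folds=folds, seed=seed, fold_aucs=fold_aucs)
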