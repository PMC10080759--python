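"""Random-forest biomarker panels with MDA selection and ROC evaluation.

Feature importance follows the randomForest convention: mean decrease
accuracy (MDA) is the per-tree drop in out-of-bag accuracy when one
feature's values are permuted among the OOB samples, averaged over trees
and normalised by its standard error.  Features with MDA above a threshold
(2.0 in the study design this mirrors) form the biomarker panel.

ROC curves are computed on out-of-fold class probabilities from stratified
cross-validation -- resubstitution ROC on n = 20 would be optimistically
biased -- and AUC by the trapezoid rule, which on ranked scores equals the
Mann-Whitney U statistic divided by n1*n2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "PanelResult",
    "auc_from_scores",
    "single_feature_auc",
    "mda_importance",
    "mda_select",
    "cv_feature_curve",
    "panel_auc",
]


@dataclass
class PanelResult:
    """Selected feature panel plus the evidence behind it."""

    features: list[str] = field(default_factory=list)
    mda: pd.Series | None = None
    cv_curve: pd.DataFrame | None = None  # columns: n_features, cv_error
    roc: pd.DataFrame | None = None  # columns: fpr, tpr
    auc: float | None = None
    oof_scores: pd.Series | None = None


def _validate_two_classes(y: np.ndarray, pos_label=None):
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if pos_label is None:
        pos_label = classes[-1]
    elif pos_label not in classes:
        raise ValueError(f"pos_label {pos_label!r} not among {list(classes)}")
    return classes, pos_label


def auc_from_scores(scores, labels, pos_label=None) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep) and trapezoid AUC from continuous scores."""
    y = np.asarray(labels)
    _, pos = _validate_two_classes(y, pos_label)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float), pos_label=pos)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc


def single_feature_auc(values, labels, pos_label=None, fold: bool = True) -> float:
    """AUC of one feature as a classifier: U/(n1*n2) with tie credit 0.5.

    ``fold=True`` direction-folds to max(AUC, 1-AUC), since a biomarker
    enriched in either group is equally usable.
    """
    y = np.asarray(labels)
    _, pos = _validate_two_classes(y, pos_label)
    v = np.asarray(values, dtype=float)
    x_pos, x_neg = v[y == pos], v[y != pos]
    u = sps.mannwhitneyu(x_pos, x_neg, alternative="two-sided").statistic
    auc = float(u) / (len(x_pos) * len(x_neg))
    return max(auc, 1.0 - auc) if fold else auc


def _bootstrap_forest(X, y, n_trees, rng, max_features="sqrt"):
    """Bagged decision trees with explicit bootstrap bookkeeping, so OOB
    membership is known per tree (sklearn's forest hides the indices)."""
    n = len(y)
    trees = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(0, 2**31))
        )
        tree.fit(X[idx], y[idx])
        trees.append((tree, oob))
    return trees


def mda_importance(
    X: pd.DataFrame, y, n_trees: int = 500, seed: int | None = None
) -> pd.Series:
    """Normalised mean-decrease-accuracy importance per feature.

    For each tree: OOB accuracy minus OOB accuracy after permuting one
    feature among the OOB samples.  MDA = mean over trees / (sd / sqrt(T));
    if the sd is zero the raw mean is reported (randomForest's convention).
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    _validate_two_classes(yv)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    trees = _bootstrap_forest(Xv, yv, n_trees, rng)

    decreases = np.full((n_trees, p), np.nan)
    for t, (tree, oob) in enumerate(trees):
        if oob.sum() < 2:
            continue
        X_oob, y_oob = Xv[oob], yv[oob]
        base_acc = (tree.predict(X_oob) == y_oob).mean()
        m = len(y_oob)
        # one batched predict: p permuted copies of the OOB block stacked
        stacked = np.tile(X_oob, (p, 1))
        for j in range(p):
            perm = rng.permutation(m)
            stacked[j * m : (j + 1) * m, j] = X_oob[perm, j]
        pred = tree.predict(stacked).reshape(p, m)
        perm_acc = (pred == y_oob).mean(axis=1)
        decreases[t] = base_acc - perm_acc

    mean = np.nanmean(decreases, axis=0)
    sd = np.nanstd(decreases, axis=0, ddof=1)
    t_used = np.sum(~np.isnan(decreases[:, 0]))
    se = sd / np.sqrt(max(t_used, 1))
    mda = np.where(se > 0, mean / np.where(se > 0, se, 1.0), mean)
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(p))
    return pd.Series(mda, index=cols, name="MDA")


def mda_select(
    X: pd.DataFrame,
    y,
    threshold: float = 2.0,
    n_trees: int = 500,
    seed: int | None = None,
) -> PanelResult:
    """Panel = features with MDA above ``threshold``, importance-ordered."""
    mda = mda_importance(X, y, n_trees=n_trees, seed=seed)
    selected = mda[mda > threshold].sort_values(ascending=False)
    return PanelResult(features=list(selected.index), mda=mda.sort_values(ascending=False))


def _feature_schedule(m: int) -> list[int]:
    """Halving schedule m, ceil(m/2), ..., 1 (the rfcv step=0.5 ladder)."""
    counts = []
    k = m
    while k >= 1:
        counts.append(k)
        if k == 1:
            break
        k = int(np.ceil(k / 2))
    return counts


def cv_feature_curve(
    X: pd.DataFrame,
    y,
    folds: int = 5,
    n_trees: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-validated error as the feature set is halved by importance.

    Within each stratified fold, features are ranked by forest importance on
    the training split only; at each count of the halving schedule a fresh
    forest on the top-k training features predicts the held-out split.
    Returns a DataFrame (n_features, cv_error).
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    classes, _ = _validate_two_classes(yv)
    counts = np.array([(yv == c).sum() for c in classes])
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; use at most that many folds"
        )
    schedule = _feature_schedule(Xv.shape[1])
    errors = {k: 0 for k in schedule}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ss = np.random.SeedSequence(seed)
    for (train, test), fold_seed in zip(skf.split(Xv, yv), ss.spawn(folds)):
        fs = int(fold_seed.generate_state(1)[0] % (2**31))
        ranker = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=fs
        )
        ranker.fit(Xv[train], yv[train])
        order = np.argsort(ranker.feature_importances_)[::-1]
        for k in schedule:
            top = order[:k]
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", random_state=fs
            )
            clf.fit(Xv[train][:, top], yv[train])
            errors[k] += int((clf.predict(Xv[test][:, top]) != yv[test]).sum())
    n = len(yv)
    return pd.DataFrame(
        {"n_features": schedule, "cv_error": [errors[k] / n for k in schedule]}
    )


def panel_auc(
    X: pd.DataFrame,
    y,
    panel: list[str] | None = None,
    folds: int = 5,
    n_trees: int = 500,
    seed: int | None = None,
    pos_label=None,
) -> PanelResult:
    """Out-of-fold ROC/AUC of a feature panel.

    Class probabilities are pooled across stratified folds before the
    threshold sweep, so every sample is scored by a model that never saw it.
    """
    if panel is not None:
        if not panel:
            raise ValueError("panel is empty")
        X = X[panel]
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    classes, pos = _validate_two_classes(yv, pos_label)
    counts = np.array([(yv == c).sum() for c in classes])
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; use at most that many folds"
        )
    oof = np.full(len(yv), np.nan)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ss = np.random.SeedSequence(seed)
    for (train, test), fold_seed in zip(skf.split(Xv, yv), ss.spawn(folds)):
        fs = int(fold_seed.generate_state(1)[0] % (2**31))
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=fs
        )
        clf.fit(Xv[train], yv[train])
        pos_col = list(clf.classes_).index(pos)
        oof[test] = clf.predict_proba(Xv[test])[:, pos_col]
    roc, auc = auc_from_scores(oof, yv, pos_label=pos)
    index = X.index if isinstance(X, pd.DataFrame) else None
    return PanelResult(
        features=list(X.columns) if isinstance(X, pd.DataFrame) else [],
        roc=roc,
        auc=auc,
        oof_scores=pd.Series(oof, index=index, name="oof_probability"),
    )
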