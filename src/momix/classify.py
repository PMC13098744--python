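"""Feature ranking, leave-one-out classification and ROC evaluation.

Features are ranked either by random-forest Gini importance (mean decrease in
Gini impurity, weighted by node sample fraction and normalized to sum 1) or
by the scatter-coefficient ratio SB/Sw, where Sw is the within-class and SB
the between-class sum-of-squares scatter of a feature.  Classification uses
leave-one-out cross-validation: for each held-out specimen, features are
ranked on the training fold only, the top k selected, a random-forest or LDA
model fitted, and the held-out positive-class probability recorded.  The ROC
curve and AUC are computed once from the accumulated probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

from .core import ParameterError, feature_modality, impute_class_means

logger = logging.getLogger("momix")

__all__ = [
    "RankedFeatures",
    "LOOResult",
    "scatter_ratio",
    "gini_importance",
    "rank_features",
    "loo_probabilities",
    "roc_auc",
    "group_comparisons",
]


@dataclass
class RankedFeatures:
    names: list
    scores: np.ndarray
    method: str


@dataclass
class LOOResult:
    probabilities: pd.Series  # per-specimen positive-class probability
    labels: pd.Series
    positive: str
    selected: list = field(default_factory=list)  # per-fold top-k feature lists
    roc: np.ndarray = None  # (n_points, 2): FPR, TPR
    auc: float = float("nan")


def scatter_ratio(feature_values, labels) -> float:
    """Between- to within-class scatter ratio SB/Sw of one feature.

    Sw = sum_i sum_j (x_j - m_i)^2 over classes i and their members j;
    SB = sum_i n_i (m_i - m)^2 with m the grand mean.  A feature that is
    constant within every class (Sw = 0) is flagged infinite — maximally
    discriminative when class means differ.
    """
    x = pd.Series(np.asarray(feature_values, dtype=float))
    labels = pd.Series(np.asarray(labels)).reindex(x.index)
    keep = x.notna()
    x, labels = x[keep], labels[keep]
    classes = labels.unique()
    if len(classes) < 2:
        raise ParameterError("scatter ratio needs at least two classes")
    grand = x.mean()
    sw = sb = 0.0
    for cls in classes:
        vals = x[labels == cls]
        mi = vals.mean()
        sw += float(((vals - mi) ** 2).sum())
        sb += len(vals) * float((mi - grand) ** 2)
    if sw == 0.0:
        return float("inf") if sb > 0 else float("nan")
    return sb / sw


def gini_importance(table: pd.DataFrame, labels, n_trees: int = 100, seed: int = 0):
    """Random-forest Gini importances per feature, normalized to sum 1."""
    X = table.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ParameterError("feature table must be imputed (finite) for Gini importance")
    y = pd.Series(labels).reindex(table.index).to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=int(seed), n_jobs=1
    )
    forest.fit(X, y)
    return pd.Series(forest.feature_importances_, index=table.columns)


def rank_features(
    table: pd.DataFrame, labels, method: str = "gini", n_trees: int = 100, seed: int = 0
) -> RankedFeatures:
    """Order features by discriminative score, best first.

    ``method="gini"`` uses random-forest importance; ``method="scatter"``
    uses the SB/Sw ratio with infinite ratios sorted above all finite values.
    Ties break lexicographically so the ranking is deterministic.
    """
    if method == "gini":
        scores = gini_importance(table, labels, n_trees=n_trees, seed=seed)
    elif method == "scatter":
        scores = pd.Series(
            {f: scatter_ratio(table[f], labels) for f in table.columns}
        )
    else:
        raise ParameterError(f"unknown ranking method {method!r}")
    keyed = sorted(
        table.columns,
        key=lambda f: (
            -np.inf if np.isposinf(scores[f]) else (-scores[f] if np.isfinite(scores[f]) else np.inf),
            f,
        ),
    )
    return RankedFeatures(keyed, scores[keyed].to_numpy(), method)


def _make_model(model: str, seed: int, n_trees: int):
    if model == "rf":
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=int(seed), n_jobs=1
        )
    if model == "lda":
        # pooled covariance with automatic shrinkage: LOO fold sizes make the
        # top-k covariance singular routinely at small n
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    raise ParameterError(f"unknown model {model!r}")


def loo_probabilities(
    table: pd.DataFrame,
    labels,
    model: str = "rf",
    k: int = 10,
    ranking: str = "gini",
    seed: int = 0,
    n_trees: int = 100,
    positive: str = "cancer",
    ranking_scope: str = "fold",
) -> LOOResult:
    """Leave-one-out classification with per-fold feature selection.

    For each held-out specimen the remaining specimens form the training
    fold; features are ranked on that fold only (``ranking_scope="fold"``,
    the leakage-safe default; ``"global"`` ranks once on all specimens), the
    top ``k`` are selected, the model fitted, and the held-out specimen's
    positive-class probability recorded.  The fixed seed makes the result
    bitwise reproducible.
    """
    labels = pd.Series(labels).reindex(table.index)
    if k > table.shape[1]:
        raise ParameterError(f"k={k} exceeds {table.shape[1]} available features")
    counts = labels.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ParameterError("need at least 2 specimens per class for leave-one-out")
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ParameterError("impute the feature table before classification")

    global_top = None
    if ranking_scope == "global":
        global_top = rank_features(table, labels, ranking, n_trees, seed).names[:k]
    elif ranking_scope != "fold":
        raise ParameterError("ranking_scope must be 'fold' or 'global'")

    probs = {}
    selected = []
    for held_out in table.index:
        train = table.drop(index=held_out)
        y_train = labels.drop(index=held_out)
        top = global_top or rank_features(train, y_train, ranking, n_trees, seed).names[:k]
        selected.append(list(top))
        clf = _make_model(model, seed + 1, n_trees)
        clf.fit(train[top].to_numpy(dtype=float), y_train.to_numpy())
        proba = clf.predict_proba(table.loc[[held_out], top].to_numpy(dtype=float))[0]
        pos_idx = list(clf.classes_).index(positive)
        probs[held_out] = float(proba[pos_idx])

    probabilities = pd.Series(probs).reindex(table.index)
    roc, auc = roc_auc(probabilities, labels, positive)
    return LOOResult(probabilities, labels, positive, selected, roc, auc)


def roc_auc(probabilities, labels, positive: str = "cancer"):
    """ROC points by threshold sweep and trapezoidal AUC.

    Thresholds sweep the unique scores from high to low; tied scores step
    simultaneously.  Returns ``(points, auc)`` with points as an (n, 2) array
    of (FPR, TPR) from (0, 0) to (1, 1).
    """
    scores = pd.Series(probabilities)
    y = pd.Series(labels).reindex(scores.index)
    pos = (y == positive).to_numpy()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ParameterError("ROC needs both classes present")
    s = scores.to_numpy(dtype=float)
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            tp += bool(pos_sorted[j])
            fp += not pos_sorted[j]
            j += 1
        points.append((fp / n0, tp / n1))
        i = j
    pts = np.asarray(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


_COMPARISONS = {
    "normal_vs_abnormal": ("normal", ("cancer", "metaplasia")),
    "normal_vs_cancer": ("normal", ("cancer",)),
    "normal_vs_metaplasia": ("normal", ("metaplasia",)),
    "metaplasia_vs_cancer": ("metaplasia", ("cancer",)),
}


def group_comparisons(
    table: pd.DataFrame,
    labels,
    config=None,
    comparisons=None,
    sources=("af", "hsi", "oct", "pli", "pooled"),
    model: str = "rf",
    k: int = 10,
    ranking: str = "gini",
) -> dict:
    """Run the LOO protocol for each class pairing and feature source.

    Each comparison pools the listed positive classes into one group (e.g.
    cancer + metaplasia = "abnormal") and runs the classifier per modality
    feature set and on the pooled multimodal set.  The headline configuration
    is a random forest with the 10 best Gini-ranked features.  Missing values
    are imputed with class means within each comparison's specimen subset.
    Returns {comparison: {source: LOOResult}}.
    """
    from .config import StudyConfig

    config = config or StudyConfig()
    labels = pd.Series(labels).reindex(table.index)
    comparisons = comparisons or list(_COMPARISONS)
    out: dict[str, dict] = {}
    modality = pd.Series({f: feature_modality(f) for f in table.columns})
    for comp in comparisons:
        negative, positives = _COMPARISONS[comp]
        sel = labels.isin([negative, *positives])
        if not sel.any() or labels[sel].nunique() < 2:
            logger.warning("comparison %s: empty group, skipped", comp)
            continue
        sub = table.loc[sel]
        y = labels[sel].map(lambda c: "positive" if c in positives else negative)
        # drop features with no observed value in either group, impute the rest
        observed = sub.groupby(y).apply(lambda b: b.notna().any(axis=0))
        usable = observed.all(axis=0)
        sub = sub.loc[:, usable[usable].index]
        sub = impute_class_means(sub, y)
        out[comp] = {}
        for source in sources:
            cols = list(sub.columns) if source == "pooled" else [
                f for f in sub.columns if modality[f] == source
            ]
            if len(cols) < k:
                logger.warning("comparison %s source %s: only %d features", comp, source, len(cols))
                continue
            out[comp][source] = loo_probabilities(
                sub[cols],
                y,
                model=model,
                k=k,
                ranking=ranking,
                seed=config.seed,
                n_trees=config.n_trees,
                positive="positive",
            )
    return out
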