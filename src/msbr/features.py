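"""Feature selection and classification over differential methylation probes.

Collinear probes are pruned greedily; the survivors go through a Boruta-style
all-relevant selection: every iteration appends column-permuted "shadow"
copies of the features, fits a random forest, scores a hit when a real
feature's importance beats the best shadow, and decides features by
two-sided binomial tests on hit counts with Bonferroni correction. Confirmed
features feed a linear max-margin classifier evaluated by stratified 10-fold
cross-validation on a 70% training split and by AUC on the held-out 30%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "BorutaResult",
    "ClassifierEval",
    "make_split",
    "prune_collinear",
    "boruta_select",
    "rough_fix",
    "train_eval",
    "compute_auc",
]


@dataclass
class SplitPlan:
    train_ids: list[str]
    heldout_ids: list[str]
    ratio: float
    seed: int


@dataclass
class BorutaResult:
    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    n_iterations: int
    importance_history: pd.DataFrame  # iteration x feature importances
    shadow_max_history: list[float] = field(default_factory=list)


@dataclass
class ClassifierEval:
    auc_train: float
    auc_cv: float
    auc_heldout: float
    model: str = "linear SVM, C=1"
    cv_fold_aucs: list[float] = field(default_factory=list)


def make_split(labels: pd.Series, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Stratified random split of sample ids into train/held-out sets."""
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples to stratify")
    train_ids, heldout_ids = train_test_split(
        list(labels.index),
        train_size=ratio,
        stratify=labels.to_numpy(),
        random_state=seed,
    )
    return SplitPlan(train_ids=list(train_ids), heldout_ids=list(heldout_ids),
                     ratio=ratio, seed=seed)


def prune_collinear(x: pd.DataFrame, r_max: float = 0.9) -> list[str]:
    """Greedy collinearity pruning over feature rows (feature x sample).

    Features are visited in descending-variance order (ties by row order);
    a feature is dropped when |Pearson r| > r_max with any already-kept
    feature. Constant features correlate with nothing and are kept.
    """
    if x.shape[0] < 2:
        raise ValueError("need at least 2 features")
    vals = x.to_numpy(dtype=float)
    variances = vals.var(axis=1)
    order = np.argsort(-variances, kind="stable")
    sd = vals.std(axis=1)
    centered = vals - vals.mean(axis=1, keepdims=True)
    kept: list[int] = []
    for i in order:
        drop = False
        for j in kept:
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = centered[i] @ centered[j] / (vals.shape[1] * sd[i] * sd[j])
            if abs(r) > r_max:
                drop = True
                break
        if not drop:
            kept.append(i)
    kept_set = set(kept)
    return [f for i, f in enumerate(x.index) if i in kept_set]


def _forest_importances(
    x: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> np.ndarray:
    rf = RandomForestClassifier(n_estimators=n_trees, n_jobs=1, random_state=seed)
    rf.fit(x, y)
    return rf.feature_importances_


def boruta_select(
    x: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    alpha: float = 0.05,
    max_iter: int = 100,
    shadows_per_feature: int = 3,
    seed: int = 0,
) -> BorutaResult:
    """All-relevant feature selection against permuted shadow features.

    ``x`` is feature x sample; ``y`` holds class labels per sample. Each
    iteration appends ``shadows_per_feature`` independently column-permuted
    shadow copies of every feature, fits a random forest (unlimited depth,
    mean-decrease-in-impurity importances), and credits a "hit" to each
    undecided real feature whose importance strictly exceeds the maximum
    shadow importance. After each iteration, two-sided binomial tests
    (p = 0.5, applied as their two one-sided halves) with Bonferroni
    correction over the input features confirm (more hits than chance) or
    reject (fewer) features. Features undecided after ``max_iter``
    iterations are tentative. Several shadow copies per feature keep the
    max-shadow bar high, which suppresses confirmation of features whose
    apparent relevance is dataset luck.
    """
    if y.nunique() < 2:
        raise ValueError("y must contain at least 2 classes")
    if x.isna().any().any():
        raise ValueError("x must not contain missing values")
    rng = np.random.default_rng(seed)
    # canonical (sorted) feature order makes the whole computation — shadow
    # permutations, forest column order, decisions — independent of the
    # caller's feature ordering
    x = x.loc[sorted(x.index)]
    features = list(x.index)
    n_features = len(features)
    data = x.to_numpy(dtype=float).T  # samples x features
    labels = y.loc[list(x.columns)].to_numpy()

    undecided = list(range(n_features))
    confirmed: set[int] = set()
    rejected: set[int] = set()
    hits = np.zeros(n_features, dtype=int)
    history = []
    shadow_max_hist: list[float] = []
    n_done = 0

    for it in range(1, max_iter + 1):
        if not undecided:
            break
        # every feature stays in the forest so the max-shadow bar keeps a
        # constant height; shrinking the shadow pool as features resolve
        # lowers the bar and lets chance-correlated survivors clear it
        cols = list(range(n_features))
        real = data[:, cols]
        shadows = []
        for _ in range(max(1, shadows_per_feature)):
            sh = real.copy()
            for c in range(sh.shape[1]):
                sh[:, c] = rng.permutation(sh[:, c])
            shadows.append(sh)
        design = np.hstack([real] + shadows)
        imp = _forest_importances(
            design, labels, n_trees, seed=int(rng.integers(0, 2**31 - 1))
        )
        real_imp, shadow_imp = imp[: len(cols)], imp[len(cols):]
        threshold = shadow_imp.max()
        shadow_max_hist.append(float(threshold))
        hit_now = real_imp > threshold
        undecided_set = set(undecided)
        for pos, c in enumerate(cols):
            if c in undecided_set:
                hits[c] += int(hit_now[pos])
        history.append(pd.Series(real_imp, index=[features[c] for c in cols], name=it))

        # decide with Bonferroni over all input features; the two-sided test
        # at level alpha is applied as its two one-sided halves, which also
        # names the direction (greater -> confirm, less -> reject)
        bonf = alpha / (2 * n_features)
        still = []
        remaining = max_iter - it
        for c in undecided:
            h = int(hits[c])
            p_greater = binomtest(h, it, p=0.5, alternative="greater").pvalue
            p_less = binomtest(h, it, p=0.5, alternative="less").pvalue
            if p_greater <= bonf:
                confirmed.add(c)
            elif p_less <= bonf:
                rejected.add(c)
            else:
                # drop features that can no longer reach either decision
                # bound even with an all-hit or all-miss tail: they are
                # destined tentative, so the loop can end early
                can_confirm = (
                    binomtest(h + remaining, max_iter, p=0.5,
                              alternative="greater").pvalue <= bonf
                )
                can_reject = (
                    binomtest(h, max_iter, p=0.5, alternative="less").pvalue <= bonf
                )
                if can_confirm or can_reject:
                    still.append(c)
        undecided = still
        n_done = it

    tentative = sorted(set(range(n_features)) - confirmed - rejected)
    hist = pd.DataFrame(history) if history else pd.DataFrame(columns=features)
    return BorutaResult(
        confirmed=[features[i] for i in sorted(confirmed)],
        tentative=[features[i] for i in tentative],
        rejected=[features[i] for i in sorted(rejected)],
        n_iterations=n_done,
        importance_history=hist,
        shadow_max_history=shadow_max_hist,
    )


def rough_fix(result: BorutaResult) -> list[str]:
    """Resolve tentative features by median importance vs. median shadow max.

    A tentative feature is accepted when its median importance across the
    recorded iterations exceeds the median of the per-iteration maximum
    shadow importances — the usual post-hoc resolution for features the
    hit-count test leaves undecided.
    """
    if not result.tentative or not result.shadow_max_history:
        return []
    bar = float(np.median(result.shadow_max_history))
    accepted = []
    for f in result.tentative:
        med = float(result.importance_history[f].median())
        if med > bar:
            accepted.append(f)
    return accepted


def compute_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute one half.

    ``labels`` must be binary with 1 marking cases.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def train_eval(
    x: pd.DataFrame,
    y: pd.Series,
    features: list[str],
    plan: SplitPlan,
    k_folds: int = 10,
    C: float = 1.0,
    kernel: str = "linear",
    seed: int = 0,
) -> ClassifierEval:
    """Linear max-margin classifier with CV on train and AUC on held-out.

    ``x`` is feature x sample. Inputs are standardized inside each fit;
    decision-function scores feed the rank-based AUC. If a stratified fold
    would lose a class, the fold count is reduced with a warning.
    """
    missing = [f for f in features if f not in set(x.index)]
    if missing:
        raise ValueError(f"unknown features: {missing[:5]}")
    sub = x.loc[features]
    # positive class = lexicographically last label, for determinism
    classes = sorted(y.unique())
    y01 = (y == classes[-1]).astype(int)

    xtr = sub[plan.train_ids].to_numpy().T
    ytr = y01.loc[plan.train_ids].to_numpy()
    xte = sub[plan.heldout_ids].to_numpy().T
    yte = y01.loc[plan.heldout_ids].to_numpy()

    min_class = int(np.bincount(ytr).min())
    k_eff = min(k_folds, min_class)
    if k_eff < k_folds:
        logger.warning("reducing CV folds from %d to %d (small class)", k_folds, k_eff)
    if k_eff < 2:
        raise ValueError("cannot cross-validate with a singleton class")

    def fit_clf(xa, ya):
        clf = make_pipeline(StandardScaler(), SVC(kernel=kernel, C=C))
        clf.fit(xa, ya)
        return clf

    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    fold_aucs = []
    for tr_idx, va_idx in skf.split(xtr, ytr):
        clf = fit_clf(xtr[tr_idx], ytr[tr_idx])
        scores = clf.decision_function(xtr[va_idx])
        if len(np.unique(ytr[va_idx])) < 2:
            continue
        fold_aucs.append(compute_auc(scores, ytr[va_idx]))

    clf = fit_clf(xtr, ytr)
    auc_train = compute_auc(clf.decision_function(xtr), ytr)
    auc_heldout = compute_auc(clf.decision_function(xte), yte)
    return ClassifierEval(
        auc_train=auc_train,
        auc_cv=float(np.mean(fold_aucs)),
        auc_heldout=auc_heldout,
        model=f"{kernel} SVM, C={C}",
        cv_fold_aucs=fold_aucs,
    )
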