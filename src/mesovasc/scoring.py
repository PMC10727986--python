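"""Microangiopathy score: composite random-forest probability of diabetes.

Per-image positive-class probabilities come from a random forest (100 trees,
unlimited depth) evaluated under leave-one-subject-out (LOSO) cross-
validation — no image of the held-out participant ever enters training, which
is asserted structurally on every run.  The participant score is the mean of
that participant's image probabilities and lies in (0, 1); the operating
threshold maximizes the Youden index (SNS + SPC - 1).  Reported metrics use
the standard confusion-count formulas:

    ACC = (TP+TN)/(TP+TN+FP+FN), SNS = TP/(TP+FN), SPC = TN/(TN+FP),
    PPV = TP/(TP+FP), NPV = TN/(TN+FN)

plus F1, a [0,1]-normalized Matthews coefficient and the AUC.  Feature
selection is univariate ANOVA-F (SelectKBest); nested cross-validation,
bootstrap confidence intervals, a class-imbalance subgroup check and a
clinical subgroup report complete the evaluation battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings: 100 fully grown Gini trees by default.

    ``class_weight="balanced"`` compensates the one-sample class imbalance
    every leave-one-subject-out training fold carries; without it held-out
    participants are scored slightly against their own class.
    """

    n_estimators: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 1
    max_features: str | int | None = "sqrt"
    max_samples: float | None = None
    class_weight: str | None = "balanced"
    random_state: int = 0

    def build(self, seed_offset: int = 0) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            max_samples=self.max_samples,
            class_weight=self.class_weight,
            criterion="gini", random_state=self.random_state + seed_offset,
            n_jobs=1)


# ---------------------------------------------------------------------------
# feature selection


def select_k_best(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the top-k features by univariate ANOVA F score.

    Deterministic: ties break toward the lower feature index; the returned
    index set is sorted ascending.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    if min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need at least 2 samples per class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield F = nan
        scores, _ = f_classif(X, y)
    scores = np.nan_to_num(scores, nan=-np.inf)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# LOSO scoring


def loso_score(X: np.ndarray, y: np.ndarray, participant_ids,
               forest: ForestConfig = ForestConfig()
               ) -> pd.DataFrame:
    """Per-image LOSO positive-class probabilities with across-tree s.d.

    For each participant a forest is trained on all other participants'
    images; leakage of the held-out participant into training is asserted.
    Returns a frame indexed like the input with columns ``participant_id``,
    ``probability``, ``tree_sd``, ``label``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    ids = np.asarray(participant_ids)
    uniq = pd.unique(ids)
    rows = np.empty(len(y), dtype=float)
    sds = np.empty(len(y), dtype=float)
    for fold, pid in enumerate(uniq):
        test = ids == pid
        train = ~test
        assert not np.any(ids[train] == pid), "LOSO leakage: held-out rows in training"
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"training fold for {pid!r} contains a single class")
        clf = forest.build(seed_offset=fold).fit(X[train], y[train])
        pos = list(clf.classes_).index(1)
        rows[test] = clf.predict_proba(X[test])[:, pos]
        per_tree = np.stack([t.predict_proba(X[test])[:, list(t.classes_).index(1)]
                             if 1 in t.classes_ else np.zeros(test.sum())
                             for t in clf.estimators_])
        sds[test] = per_tree.std(axis=0)
    return pd.DataFrame({"participant_id": ids, "probability": rows,
                         "tree_sd": sds, "label": y})


def participant_score(image_scores: pd.DataFrame) -> pd.DataFrame:
    """Mean image probability per participant (the microangiopathy score)."""
    if image_scores["participant_id"].isna().any():
        raise ValueError("image with no participant mapping")
    g = image_scores.groupby("participant_id", sort=False)
    out = g.agg(score=("probability", "mean"), tree_sd=("tree_sd", "mean"),
                label=("label", "first"))
    return out


# ---------------------------------------------------------------------------
# threshold and metrics


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cut maximizing J = SNS + SPC - 1; positive decision is score > t.

    Candidate cuts are the midpoints between consecutive distinct scores plus
    sentinels outside the range.  Ties resolve to the middle of the lowest
    contiguous run of optimal candidates, so a perfectly separating gap
    yields its midpoint and equal-J plateaus prefer the lower cut.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    s = np.unique(scores)
    cands = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    js = np.array([
        ((scores > t) & (labels == 1)).sum() / n_pos
        + ((scores <= t) & (labels == 0)).sum() / n_neg - 1.0
        for t in cands])
    best = np.flatnonzero(js >= js.max() - 1e-12)
    run_end = 0
    while run_end + 1 < len(best) and best[run_end + 1] == best[run_end] + 1:
        run_end += 1
    first_run = best[:run_end + 1]
    return float(cands[first_run[len(first_run) // 2]])


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class Metrics:
    acc: float | None
    sns: float | None
    spc: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    mcc_normalized: float | None
    auc: float | None = None
    counts: ConfusionCounts | None = None
    undefined: list[str] = field(default_factory=list)


def confusion_counts(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores > threshold
    return ConfusionCounts(
        TP=int((pred & (labels == 1)).sum()),
        TN=int((~pred & (labels == 0)).sum()),
        FP=int((pred & (labels == 0)).sum()),
        FN=int((~pred & (labels == 1)).sum()))


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = ratio(c.TP + c.TN, c.total, "acc")
    sns = ratio(c.TP, c.TP + c.FN, "sns")
    spc = ratio(c.TN, c.TN + c.FP, "spc")
    ppv = ratio(c.TP, c.TP + c.FP, "ppv")
    npv = ratio(c.TN, c.TN + c.FN, "npv")
    f1 = (None if ppv is None or sns is None or (ppv + sns) == 0
          else 2 * ppv * sns / (ppv + sns))
    denom = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    if denom == 0:
        mcc_n = None
        undefined.append("mcc")
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
        mcc_n = (mcc + 1.0) / 2.0
    return Metrics(acc=acc, sns=sns, spc=spc, ppv=ppv, npv=npv, f1=f1,
                   mcc_normalized=mcc_n, counts=c, undefined=undefined)


def classification_metrics(scores, labels, threshold: float) -> Metrics:
    """All printed-formula metrics at the given cut, plus the AUC."""
    c = confusion_counts(scores, labels, threshold)
    m = metrics_from_counts(c)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) == 2:
        m.auc = float(roc_auc_score(labels, np.asarray(scores, float)))
    return m


def auc_confidence_interval(X, y, participant_ids,
                            forest: ForestConfig = ForestConfig(),
                            n_iterations: int = 100, seed: int = 0,
                            alpha: float = 0.05) -> tuple[float, float]:
    """Percentile AUC interval over refits with resampled training cohorts.

    Each iteration bootstraps participants into a training set, scores the
    out-of-bag participants and records their AUC.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    ids = np.asarray(participant_ids)
    uniq = pd.unique(ids)
    rng = np.random.default_rng(seed)
    aucs = []
    for it in range(n_iterations):
        boot = rng.choice(uniq, size=len(uniq), replace=True)
        train = np.isin(ids, boot)
        test = ~train
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            continue
        clf = forest.build(seed_offset=1000 + it).fit(X[train], y[train])
        pos = list(clf.classes_).index(1)
        prob = clf.predict_proba(X[test])[:, pos]
        per_part = pd.DataFrame({"pid": ids[test], "p": prob, "y": y[test]}
                                ).groupby("pid").agg(p=("p", "mean"), y=("y", "first"))
        if per_part["y"].nunique() == 2:
            aucs.append(roc_auc_score(per_part["y"], per_part["p"]))
    if not aucs:
        raise RuntimeError("no iteration produced a two-class out-of-bag split")
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class NestedCVResult:
    k_star: tuple[float, float]          # mean, sd
    auc: tuple[float, float]
    acc: tuple[float, float]
    sns: tuple[float, float]
    spc: tuple[float, float]
    ppv: tuple[float, float]
    npv: tuple[float, float]
    per_trial: pd.DataFrame = None


def nested_cv(X, y, participant_ids, n_trials: int = 30,
              k_grid=None, estimator_grid=(50, 100, 200),
              max_features_grid=("sqrt", "log2", None),
              inner_folds: int = 4, seed: int = 0) -> NestedCVResult:
    """Outer LOSO, inner 4-fold grid search over forest size/max-features/k.

    Reports mean +/- s.d. of the selected k and of the outer metrics across
    trials (each trial reshuffles the inner folds).
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    ids = np.asarray(participant_ids)
    uniq = pd.unique(ids)
    if len(uniq) < inner_folds + 1:
        raise ValueError("cohort too small for the inner folds")
    if k_grid is None:
        k_grid = list(range(10, min(64, X.shape[1]) + 1))
    k_grid = [k for k in k_grid if k <= X.shape[1]]
    trials = []
    for trial in range(n_trials):
        probs = np.empty(len(y))
        ks = []
        for fold, pid in enumerate(uniq):
            test = ids == pid
            train = ~test
            pipe = Pipeline([("select", SelectKBest(f_classif)),
                             ("rf", RandomForestClassifier(random_state=seed + trial,
                                                           n_jobs=1))])
            grid = {"select__k": k_grid,
                    "rf__n_estimators": list(estimator_grid),
                    "rf__max_features": list(max_features_grid)}
            inner = KFold(n_splits=inner_folds, shuffle=True,
                          random_state=seed * 1000 + trial)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gs = GridSearchCV(pipe, grid, cv=inner, scoring="roc_auc",
                                  n_jobs=1).fit(X[train], y[train])
            ks.append(gs.best_params_["select__k"])
            pos = list(gs.best_estimator_.classes_).index(1)
            probs[test] = gs.best_estimator_.predict_proba(X[test])[:, pos]
        part = pd.DataFrame({"pid": ids, "p": probs, "y": y}).groupby("pid").agg(
            p=("p", "mean"), y=("y", "first"))
        t = youden_threshold(part["p"].values, part["y"].values)
        m = classification_metrics(part["p"].values, part["y"].values, t)
        trials.append({"k": float(np.mean(ks)), "auc": m.auc, "acc": m.acc,
                       "sns": m.sns, "spc": m.spc, "ppv": m.ppv, "npv": m.npv})
    df = pd.DataFrame(trials)

    def ms(col):
        return (float(df[col].mean()), float(df[col].std(ddof=1)) if len(df) > 1 else 0.0)

    return NestedCVResult(k_star=ms("k"), auc=ms("auc"), acc=ms("acc"),
                          sns=ms("sns"), spc=ms("spc"), ppv=ms("ppv"),
                          npv=ms("npv"), per_trial=df)


# ---------------------------------------------------------------------------
# bootstrap, imbalance, importances, subgroups


def bootstrap_eval(model, X_test, y_test, threshold: float = 0.5,
                   B: int = 1000, seed: int = 0, alpha: float = 0.05
                   ) -> dict[str, dict[str, float]]:
    """Percentile CIs for the metric battery over B test-set resamples."""
    if B < 2:
        raise ValueError("B must be >= 2")
    X_test = np.asarray(X_test, float)
    y_test = np.asarray(y_test).astype(int)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    pos = list(model.classes_).index(1)
    prob = model.predict_proba(X_test)[:, pos]
    rng = np.random.default_rng(seed)
    names = ("auc", "acc", "sns", "spc", "ppv", "npv")
    samples: dict[str, list[float]] = {n: [] for n in names}
    for _ in range(B):
        idx = rng.integers(0, len(y_test), size=len(y_test))
        m = classification_metrics(prob[idx], y_test[idx], threshold)
        for n in names:
            v = getattr(m, n)
            if v is not None:
                samples[n].append(v)
    point = classification_metrics(prob, y_test, threshold)
    out = {}
    for n in names:
        v = getattr(point, n)
        if v is None or not samples[n]:
            continue
        lo, hi = np.quantile(samples[n], [alpha / 2, 1 - alpha / 2])
        out[n] = {"value": float(v), "ci_low": float(min(lo, v)),
                  "ci_high": float(max(hi, v))}
    return out


def imbalance_check(scores, labels, subgroup_size: int = 40,
                    n_subsets: int = 5000, seed: int = 0) -> dict:
    """Median scores over random fixed-size positive-class subgroups.

    Controls for cohort imbalance: the negative class is compared against
    many random positive subgroups of the negative class's size.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if subgroup_size > len(pos):
        raise ValueError("subgroup_size exceeds the positive class size")
    rng = np.random.default_rng(seed)
    medians = np.array([np.median(rng.choice(pos, size=subgroup_size, replace=False))
                        for _ in range(n_subsets)])
    lo, hi = np.quantile(medians, [0.025, 0.975])
    return {
        "patient_median": float(np.median(medians)),
        "patient_ci": (float(lo), float(hi)),
        "healthy_median": float(np.median(neg)),
        "subset_medians": medians,
        "frac_patient_above_healthy": float(np.mean(medians > np.median(neg))),
    }


def gini_importance(fitted_forest) -> np.ndarray:
    """Normalized mean-impurity-decrease importances (sum to 1)."""
    if not hasattr(fitted_forest, "estimators_"):
        raise ValueError("forest is not fitted")
    imp = np.asarray(fitted_forest.feature_importances_, dtype=float)
    return imp


def subgroup_report(predictions_correct, metadata: pd.DataFrame
                    ) -> pd.DataFrame:
    """Proportion of truly/falsely classified individuals per clinical subgroup.

    ``metadata`` holds one categorical column per subgroup axis; empty levels
    are omitted with a warning.  Proportions sum to 1 within each subgroup.
    """
    correct = np.asarray(predictions_correct, dtype=bool)
    rows = []
    for col in metadata.columns:
        for level, sub in metadata.groupby(col, observed=True, dropna=True):
            idx = sub.index
            if len(idx) == 0:
                warnings.warn(f"empty subgroup {col}={level!r} omitted")
                continue
            c = correct[metadata.index.get_indexer(idx)]
            rows.append({"subgroup": col, "level": level, "n": len(idx),
                         "prop_correct": float(c.mean()),
                         "prop_incorrect": float(1.0 - c.mean())})
    return pd.DataFrame(rows)
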