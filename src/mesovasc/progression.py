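"""Ordinal modelling of diabetes stage and confounder control.

Stage groups A (no complications), B (neuropathy or ASCVD), C (both) are
ordered; the cumulative link model

    G^{-1}[P(Y <= j)] = a_j - X b

relates the feature vector X to stage with strictly ascending thresholds a_j
and link G (logistic by default, probit by config).  Features are z-scored
before fitting for optimizer stability; coefficients are reported on both
scales.  Model search combines bidirectional stepwise AIC over main effects
plus screened pairwise interactions with a leave-one-out accuracy
elimination, and per-scale importance is the accuracy drop after removing a
scale's features.  Confounding by age or sex is assessed with three nested
binomial-logit GLMs compared by chi-squared tests on deviance differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel


# ---------------------------------------------------------------------------
# cumulative link model


@dataclass
class OrdinalModelFit:
    """Fitted cumulative link model P(Y<=j) = G(a_j - X b)."""

    thresholds: np.ndarray               # (J-1,) strictly ascending, standardized scale
    beta: np.ndarray                     # standardized-X coefficients
    beta_se: np.ndarray
    link: str                            # "logit" | "probit"
    classes: tuple                       # ordered class labels
    terms: tuple[str, ...]
    llf: float
    aic: float
    converged: bool
    x_mean: np.ndarray = field(default=None)
    x_std: np.ndarray = field(default=None)

    @property
    def beta_raw(self) -> np.ndarray:
        """Coefficients on the original feature scale."""
        if len(self.beta) == 0:
            return self.beta
        return self.beta / self.x_std

    @property
    def thresholds_raw(self) -> np.ndarray:
        if len(self.beta) == 0:
            return self.thresholds
        return self.thresholds - float(self.beta @ (self.x_mean / self.x_std))

    def _cdf(self, z: np.ndarray) -> np.ndarray:
        return stats.logistic.cdf(z) if self.link == "logit" else stats.norm.cdf(z)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if len(self.beta) == 0:
            return np.zeros(X.shape[0])
        if X.shape[1] != len(self.beta):
            raise ValueError(f"expected {len(self.beta)} features, got {X.shape[1]}")
        Xs = (X - self.x_mean) / self.x_std
        return Xs @ self.beta

    def class_probabilities(self, X: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(X)
        cum = self._cdf(self.thresholds[None, :] - eta[:, None])
        cum = np.concatenate([np.zeros((len(eta), 1)), cum,
                              np.ones((len(eta), 1))], axis=1)
        return np.diff(cum, axis=1)


def _link_inv(link: str):
    if link == "logit":
        return stats.logistic.ppf
    if link == "probit":
        return stats.norm.ppf
    raise ValueError(f"unknown link {link!r}")


def fit_clm(X, y_ordinal, link: str = "logit",
            feature_names: tuple[str, ...] | None = None) -> OrdinalModelFit:
    """Maximum-likelihood cumulative link fit.

    ``y_ordinal`` holds ordered class labels (e.g. "A" < "B" < "C" by sorted
    order, or an ordered pandas Categorical).  With no features the
    closed-form MLE a_j = G^{-1}(cumulative class fraction) is returned.
    Non-convergence is reported on the result, never silently dropped.
    """
    y = pd.Series(y_ordinal)
    if isinstance(y.dtype, pd.CategoricalDtype) and y.cat.ordered:
        classes = tuple(y.cat.categories)
    else:
        classes = tuple(sorted(pd.unique(y)))
    codes = y.map({c: i for i, c in enumerate(classes)}).to_numpy()
    counts = np.bincount(codes, minlength=len(classes))
    if len(classes) < 2 or np.any(counts == 0):
        raise ValueError("need >=2 ordered classes, each non-empty")
    n = len(codes)

    X = np.asarray(X, dtype=float) if X is not None else np.empty((n, 0))
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))

    if X.shape[1] == 0:
        cum = np.cumsum(counts)[:-1] / n
        thresholds = _link_inv(link)(cum)
        p = counts / n
        llf = float(np.sum(counts * np.log(p)))
        k = len(classes) - 1
        return OrdinalModelFit(thresholds=thresholds, beta=np.empty(0),
                               beta_se=np.empty(0), link=link, classes=classes,
                               terms=(), llf=llf, aic=2 * k - 2 * llf,
                               converged=True,
                               x_mean=np.empty(0), x_std=np.empty(0))

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=0)
    x_std[x_std == 0] = 1.0
    Xs = (X - x_mean) / x_std

    endog = pd.Series(pd.Categorical(codes, categories=range(len(classes)),
                                     ordered=True))
    model = OrderedModel(endog, Xs, distr=link)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=0)
    converged = bool(res.mle_retvals.get("converged", True))
    kx = X.shape[1]
    beta = np.asarray(res.params[:kx], float)
    beta_se = np.asarray(res.bse[:kx], float)
    # threshold params are (a_1, log increments); recover ascending a_j
    thresholds = np.asarray(
        model.transform_threshold_params(res.params)[1:-1], float)
    if np.any(np.diff(thresholds) <= 0):
        converged = False
    return OrdinalModelFit(thresholds=thresholds, beta=beta, beta_se=beta_se,
                           link=link, classes=classes, terms=feature_names,
                           llf=float(res.llf), aic=float(res.aic),
                           converged=converged, x_mean=x_mean, x_std=x_std)


def predict_stage(model: OrdinalModelFit, X) -> pd.DataFrame:
    """Class probabilities, linear predictor and argmax class per row."""
    probs = model.class_probabilities(X)
    eta = model.linear_predictor(X)
    df = pd.DataFrame(probs, columns=[f"p_{c}" for c in model.classes])
    df["linear_predictor"] = eta
    df["predicted"] = [model.classes[i] for i in probs.argmax(axis=1)]
    return df


def _accuracy(model: OrdinalModelFit, X, y) -> float:
    pred = predict_stage(model, X)["predicted"].to_numpy()
    return float(np.mean(pred == np.asarray(y)))


# ---------------------------------------------------------------------------
# model selection


def interaction_candidates(X: pd.DataFrame, y, max_terms: int = 50
                           ) -> pd.DataFrame:
    """Main effects plus univariately screened pairwise interactions.

    The pool of pairwise products is capped at ``max_terms`` columns by an
    ANOVA-F screen against the stage labels.
    """
    X = pd.DataFrame(X)
    inter = {}
    for a, b in itertools.combinations(X.columns, 2):
        inter[f"{a}*{b}"] = X[a] * X[b]
    if not inter:
        return X
    inter = pd.DataFrame(inter, index=X.index)
    codes = pd.Series(y).map({c: i for i, c in enumerate(sorted(pd.unique(y)))})
    from sklearn.feature_selection import f_classif

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, _ = f_classif(inter.to_numpy(), codes.to_numpy())
    scores = np.nan_to_num(scores, nan=-np.inf)
    keep = inter.columns[np.argsort(-scores)][:max(max_terms - X.shape[1], 0)]
    return pd.concat([X, inter[keep]], axis=1)


def stepwise_select(X: pd.DataFrame, y, link: str = "logit",
                    max_iter: int = 100) -> OrdinalModelFit:
    """Greedy bidirectional AIC search starting from the intercept-only model.

    At each step the single add-or-drop move with the largest AIC decrease is
    taken; the search stops at a local AIC minimum, so the selected model's
    AIC never exceeds the starting model's.
    """
    X = pd.DataFrame(X)
    current: list[str] = []

    def fit(terms):
        sub = X[terms].to_numpy() if terms else None
        return fit_clm(sub, y, link=link, feature_names=tuple(terms))

    best = fit(current)
    for _ in range(max_iter):
        moves = []
        for col in X.columns:
            if col not in current:
                moves.append(current + [col])
        for col in current:
            moves.append([c for c in current if c != col])
        improved = None
        for terms in moves:
            try:
                cand = fit(terms)
            except Exception:
                continue
            if cand.aic < best.aic - 1e-9 and (improved is None
                                               or cand.aic < improved.aic):
                improved = cand
        if improved is None:
            break
        best = improved
        current = list(best.terms)
    return best


def loo_accuracy(X: pd.DataFrame, y, terms, link: str = "logit") -> float:
    """Leave-one-out classification accuracy of a CLM on the given terms."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    correct = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        try:
            m = fit_clm(X.loc[mask, list(terms)].to_numpy() if terms else None,
                        y[mask], link=link, feature_names=tuple(terms))
            pred = predict_stage(m, X.iloc[[i]][list(terms)].to_numpy()
                                 if terms else np.empty((1, 0)))
            correct += pred["predicted"].iloc[0] == y[i]
        except Exception:
            continue
    return correct / len(y)


def loo_accuracy_elimination(X: pd.DataFrame, y, model: OrdinalModelFit,
                             link: str = "logit") -> OrdinalModelFit:
    """Drop terms whose removal does not decrease LOO accuracy.

    Greedy: repeatedly removes the term with the best post-removal LOO
    accuracy as long as accuracy does not fall; stops at a local optimum.
    """
    X = pd.DataFrame(X)
    terms = list(model.terms)
    acc = loo_accuracy(X, y, terms, link)
    while terms:
        best_drop, best_acc = None, acc
        for t in terms:
            reduced = [u for u in terms if u != t]
            a = loo_accuracy(X, y, reduced, link)
            if a >= best_acc:
                best_drop, best_acc = t, a
        if best_drop is None:
            break
        terms.remove(best_drop)
        acc = best_acc
    return fit_clm(X[terms].to_numpy() if terms else None, y, link=link,
                   feature_names=tuple(terms))


@dataclass
class ScaleImportance:
    reference_accuracy: float
    drop: dict[str, float]
    subset_stats: dict[str, dict[str, float]]


def scale_removal_importance(X: pd.DataFrame, y, scale_map: dict[str, str],
                             link: str = "logit", n_subsets: int = 200,
                             subset_seed: int = 0,
                             accuracy: str = "insample") -> ScaleImportance:
    """Accuracy decrease when each scale's features are removed from the model.

    Also samples random within-scale feature subsets and reports the median
    and central 85% interval of the resulting drops (boxplot statistics).  A
    scale with no features present drops exactly 0.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)

    def acc_of(cols) -> float:
        cols = list(cols)
        m = fit_clm(X[cols].to_numpy() if cols else None, y, link=link,
                    feature_names=tuple(cols))
        if accuracy == "loo":
            return loo_accuracy(X, y, cols, link)
        return _accuracy(m, X[cols].to_numpy() if cols else np.empty((len(y), 0)), y)

    ref = acc_of(X.columns)
    scales = sorted(set(scale_map.values()))
    drop: dict[str, float] = {}
    subset_stats: dict[str, dict[str, float]] = {}
    rng = np.random.default_rng(subset_seed)
    for scale in scales:
        members = [c for c in X.columns if scale_map.get(c) == scale]
        if not members:
            drop[scale] = 0.0
            subset_stats[scale] = {"median": 0.0, "lo85": 0.0, "hi85": 0.0}
            continue
        kept = [c for c in X.columns if c not in members]
        drop[scale] = ref - acc_of(kept)
        if n_subsets > 0 and len(members) > 1:
            drops = []
            for _ in range(n_subsets):
                size = int(rng.integers(1, len(members) + 1))
                sub = list(rng.choice(members, size=size, replace=False))
                keep2 = [c for c in X.columns if c not in sub]
                drops.append(ref - acc_of(keep2))
            lo, med, hi = np.quantile(drops, [0.075, 0.5, 0.925])
            subset_stats[scale] = {"median": float(med), "lo85": float(lo),
                                   "hi85": float(hi)}
        else:
            subset_stats[scale] = {"median": drop[scale], "lo85": drop[scale],
                                   "hi85": drop[scale]}
    return ScaleImportance(reference_accuracy=ref, drop=drop,
                           subset_stats=subset_stats)


# ---------------------------------------------------------------------------
# trends and tests


@dataclass
class TrendFlag:
    feature: str
    direction: str                       # increase | decrease | none
    p_values: dict[str, float]           # contrasts A_vs_B, B_vs_C, A_vs_C
    group_means: dict[str, float]


def two_sided_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-sided p.

    Zero pooled variance with equal means returns (0, 1) by convention.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def monotonic_trends(feature_matrix: pd.DataFrame, stages) -> list[TrendFlag]:
    """Flag features whose group means are strictly ordered across A -> B -> C."""
    stages = pd.Series(np.asarray(stages), index=feature_matrix.index)
    order = sorted(stages.unique())
    if len(order) != 3:
        raise ValueError("expected exactly three stage groups")
    flags = []
    for col in feature_matrix.columns:
        means = {g: float(feature_matrix.loc[stages == g, col].mean())
                 for g in order}
        a, b, c = (means[g] for g in order)
        if a > b > c:
            direction = "decrease"
        elif a < b < c:
            direction = "increase"
        else:
            direction = "none"
        pv = {}
        for (g1, g2) in ((order[0], order[1]), (order[1], order[2]),
                         (order[0], order[2])):
            _, p = two_sided_t_test(feature_matrix.loc[stages == g1, col],
                                    feature_matrix.loc[stages == g2, col])
            pv[f"{g1}_vs_{g2}"] = p
        flags.append(TrendFlag(feature=col, direction=direction, p_values=pv,
                               group_means=means))
    return flags


# ---------------------------------------------------------------------------
# confounder control


@dataclass
class GlmComparison:
    deviances: dict[str, float]
    coef_tables: dict[str, pd.DataFrame]
    chi2_1_vs_2: tuple[float, float, int]    # statistic, p, df
    chi2_2_vs_3: tuple[float, float, int]
    separation_flag: bool


def confounder_glms(score, covariate, label) -> GlmComparison:
    """Three nested binomial-logit GLMs testing the score beyond a covariate.

    Model 1: label ~ covariate; model 2: + score; model 3: + interaction.
    Deviance differences are referred to chi-squared with df = added terms.
    """
    score = np.asarray(score, float)
    cov = np.asarray(covariate, float)
    label = np.asarray(label).astype(int)
    n = len(label)
    designs = {
        "model1": np.column_stack([np.ones(n), cov]),
        "model2": np.column_stack([np.ones(n), cov, score]),
        "model3": np.column_stack([np.ones(n), cov, score, cov * score]),
    }
    deviances, tables = {}, {}
    separation = False
    for name, Xd in designs.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(label, Xd, family=sm.families.Binomial()).fit()
        deviances[name] = float(res.deviance)
        if np.any(np.abs(res.params) > 50) or np.any(~np.isfinite(res.bse)):
            separation = True
        tables[name] = pd.DataFrame({"coef": res.params, "se": res.bse,
                                     "p": res.pvalues})

    def chi2(m_small, m_big, df):
        d = deviances[m_small] - deviances[m_big]
        d = max(d, 0.0)
        return (float(d), float(stats.chi2.sf(d, df)), df)

    return GlmComparison(deviances=deviances, coef_tables=tables,
                         chi2_1_vs_2=chi2("model1", "model2", 1),
                         chi2_2_vs_3=chi2("model2", "model3", 1),
                         separation_flag=separation)
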