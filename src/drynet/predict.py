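"""Drug-sensitivity prediction from temporal-pattern similarity.

A test cell line is classified by comparing the temporal expression
patterns of a small marker-gene panel against sensitive and resistant
reference lines.  Per gene, similarity is measured by dynamic time warping
(DTW) of z-normalized trajectories; the paired per-gene distance
differences are tested with an exact one-tailed Wilcoxon signed-rank test,
and a bootstrap over random gene sets assesses whether the chosen panel is
better than chance.  An importance-weighted L1 logistic model scores
cohort samples for sensitivity from the expression of prioritized genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from scipy.stats import rankdata

from .preprocess import TimeCourseMatrix

__all__ = [
    "dtw_distance",
    "exact_signed_rank_p",
    "SimilarityReport",
    "classify_cell_line",
    "bootstrap_set_test",
    "drynb_fit",
    "DrynbModel",
    "roc_auc",
]


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def dtw_distance(a: np.ndarray, b: np.ndarray, normalize: bool = True) -> float:
    """Classic dynamic time warping distance between two series.

    Local cost is the absolute difference; steps are the symmetric unit
    moves (match, insert, delete) with no warping window.  With
    ``normalize`` each series is z-normalized first so only the temporal
    shape is compared, not the expression scale.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires nonempty series")
    if normalize:
        a, b = _znorm(a), _znorm(b)
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    cost = np.abs(a[:, None] - b[None, :])
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = cost[i - 1, j - 1] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Null counts of the doubled positive-rank sum over all sign patterns.

    Equivalent to enumerating all 2^n sign assignments: the generating
    polynomial prod_k (1 + z^{2 r_k}) gives, per doubled rank sum w, the
    number of assignments reaching it.  Doubling keeps average tie ranks
    integral.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def exact_signed_rank_p(differences: np.ndarray, alternative: str = "less") -> float:
    """Exact one-tailed Wilcoxon signed-rank p-value.

    Zeros are dropped; |differences| are ranked with average ties, and the
    exact null distribution of the positive-rank sum W+ is computed (all
    2^n sign assignments equally likely).  ``alternative='less'`` tests a
    negative location shift (small W+), ``'greater'`` a positive one.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    d = np.asarray(differences, dtype=float).ravel()
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    ranks2 = np.rint(2 * rankdata(np.abs(d))).astype(int)
    w_plus = int(ranks2[d > 0].sum())
    counts = _signed_rank_distribution(ranks2)
    n_total = counts.sum()
    if alternative == "less":
        return float(counts[: w_plus + 1].sum() / n_total)
    return float(counts[w_plus:].sum() / n_total)


@dataclass
class SimilarityReport:
    """Outcome of the marker-panel similarity classification."""

    markers: list[str]
    dist_sensitive: pd.Series
    dist_resistant: pd.Series
    D_S: float
    D_R: float
    d: float
    p_sensitive: float
    p_resistant: float
    p_value: float
    label: str
    alpha: float = 0.05
    metric: str = "dtw"

    def to_dict(self) -> dict:
        return {
            "markers": self.markers,
            "dist_sensitive": self.dist_sensitive.to_dict(),
            "dist_resistant": self.dist_resistant.to_dict(),
            "D_S": self.D_S,
            "D_R": self.D_R,
            "d": self.d,
            "p_sensitive": self.p_sensitive,
            "p_resistant": self.p_resistant,
            "p_value": self.p_value,
            "label": self.label,
            "alpha": self.alpha,
            "metric": self.metric,
        }


def _series_distance(a: np.ndarray, b: np.ndarray, metric: str, normalize: bool) -> float:
    if metric == "dtw":
        return dtw_distance(a, b, normalize=normalize)
    if normalize:
        a, b = _znorm(np.asarray(a, float)), _znorm(np.asarray(b, float))
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "manhattan":
        return float(np.sum(np.abs(a - b)))
    raise ValueError(f"unknown metric {metric!r}")


def _panel_distances(
    test: TimeCourseMatrix,
    ref: TimeCourseMatrix,
    markers: list[str],
    metric: str,
    normalize: bool,
) -> pd.Series:
    vals = []
    for g in markers:
        a = test.values[test.gene_ids.index(g)]
        b = ref.values[ref.gene_ids.index(g)]
        vals.append(_series_distance(a, b, metric, normalize))
    return pd.Series(vals, index=list(markers))


def classify_cell_line(
    test: TimeCourseMatrix,
    sens: TimeCourseMatrix,
    res: TimeCourseMatrix,
    markers: list[str],
    alpha: float = 0.05,
    metric: str = "dtw",
    normalize: bool = True,
) -> SimilarityReport:
    """Label a test line sensitive/resistant by marker-panel DTW similarity.

    Per marker gene the distances to the sensitive and resistant reference
    trajectories are computed; the paired differences (to-sensitive minus
    to-resistant) go through the exact one-tailed signed-rank test in both
    directions, and the line is labelled when one direction reaches
    ``alpha`` — otherwise 'uncalled'.
    """
    for name, mat in (("test", test), ("sensitive", sens), ("resistant", res)):
        missing = [g for g in markers if g not in mat.gene_ids]
        if missing:
            raise KeyError(f"markers absent from {name} matrix: {missing}")
    dS = _panel_distances(test, sens, markers, metric, normalize)
    dR = _panel_distances(test, res, markers, metric, normalize)
    diffs = (dS - dR).to_numpy()
    p_sens = exact_signed_rank_p(diffs, "less")
    p_res = exact_signed_rank_p(diffs, "greater")
    if p_sens <= alpha:
        label, p = "sensitive", p_sens
    elif p_res <= alpha:
        label, p = "resistant", p_res
    else:
        label, p = "uncalled", min(p_sens, p_res)
    return SimilarityReport(
        markers=list(markers),
        dist_sensitive=dS,
        dist_resistant=dR,
        D_S=float(dS.mean()),
        D_R=float(dR.mean()),
        d=float(dS.mean() - dR.mean()),
        p_sensitive=p_sens,
        p_resistant=p_res,
        p_value=p,
        label=label,
        alpha=alpha,
        metric=metric,
    )


def bootstrap_set_test(
    observed_markers: list[str],
    deg_pool: list[str],
    test: TimeCourseMatrix,
    sens: TimeCourseMatrix,
    res: TimeCourseMatrix,
    n_iter: int = 1000,
    seed: int = 0,
    metric: str = "dtw",
    normalize: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Gene-set significance by bootstrap over random marker panels.

    Draws ``n_iter`` random panels of the observed size from ``deg_pool``,
    computes the null summary D = D_S - D_R for each, and returns
    (p, d_observed, null distribution) with the add-one-corrected
    empirical probability p = (1 + #{D_null < d_obs}) / (n_iter + 1) —
    small when the observed panel is unusually closer to the sensitive
    reference than random panels are.
    """
    k = len(observed_markers)
    if len(deg_pool) < k:
        raise ValueError(
            f"pool of {len(deg_pool)} genes smaller than marker set size {k}"
        )
    rng = np.random.default_rng(seed)
    obs = classify_cell_line(test, sens, res, observed_markers, metric=metric,
                             normalize=normalize)
    pool = np.asarray(deg_pool, dtype=object)
    null = np.empty(n_iter)
    for it in range(n_iter):
        panel = list(rng.choice(pool, size=k, replace=False))
        dS = _panel_distances(test, sens, panel, metric, normalize)
        dR = _panel_distances(test, res, panel, metric, normalize)
        null[it] = dS.mean() - dR.mean()
    p = (1 + int(np.sum(null < obs.d))) / (n_iter + 1)
    return float(p), obs.d, null


@dataclass
class DrynbModel:
    """Importance-weighted L1 logistic sensitivity model.

    Coefficients act on training-standardized expression; ``mu``/``sd``
    store the training moments so scoring applies the same transform.
    """

    genes: list[str]
    coef: pd.Series
    intercept: float
    mu: np.ndarray
    sd: np.ndarray
    selected: list[str] = field(default_factory=list)

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Per-sample sensitivity score (linear predictor)."""
        X = expr.loc[self.genes].to_numpy(dtype=float).T
        Z = (X - self.mu) / np.where(self.sd > 0, self.sd, 1.0)
        return pd.Series(Z @ self.coef.to_numpy() + self.intercept,
                         index=list(expr.columns), name="sensitivity_score")


def drynb_fit(
    expr: pd.DataFrame,
    labels: np.ndarray,
    importance: pd.Series,
    seed: int = 0,
    folds: int = 10,
    Cs: int = 10,
    invert_weighting: bool = False,
) -> DrynbModel:
    """Fit the differential-network biomarker model on a cohort.

    ``expr`` is genes x patients, ``labels`` binary response (1 =
    sensitive), ``importance`` the per-gene importance index.  Each gene's
    L1 penalty is scaled proportional to 1/importance (high-importance
    genes are shrunk less; ``invert_weighting`` flips the direction), the
    overall penalty strength is chosen by stratified ``folds``-fold CV,
    and coefficients are returned on the standardized-expression scale.
    """
    genes = [g for g in expr.index if g in importance.index]
    if len(genes) < 1:
        raise ValueError("no overlap between expression genes and importance")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = expr.loc[genes].to_numpy(dtype=float).T
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)

    w = importance.loc[genes].to_numpy(dtype=float)
    w = np.clip(w, 1e-12, None)
    scale = (1.0 / w) if invert_weighting else w
    scale = scale / scale.mean()  # mean-1 so uniform importance == plain L1
    Zw = Z * scale

    folds = min(folds, int(np.min(np.bincount(y))))
    model = LogisticRegressionCV(
        Cs=Cs, cv=folds, penalty="l1", solver="liblinear",
        random_state=seed, max_iter=5000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # sklearn API transition
        model.fit(Zw, y)
    coef = model.coef_.ravel() * scale  # back to unweighted standardized scale
    series = pd.Series(coef, index=genes, name="coef")
    selected = [g for g, c in series.items() if c != 0]
    return DrynbModel(genes, series, float(model.intercept_[0]), mu, sd, selected)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic ROC AUC (ties credited 0.5)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
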