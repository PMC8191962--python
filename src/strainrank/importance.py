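"""Multi-method feature-importance estimation for the strain feature table.

Methods
-------
* :func:`oob_importance` — a random forest of 700 gini trees, each grown on
  a bootstrap sample and a random subspace of 10 features; importance of a
  feature is the mean decrease in out-of-bag accuracy when that feature's
  OOB column is permuted, averaged over the trees that used it, normalized
  so the most important feature scores 1.
* :func:`correlation_graph` — pairwise Pearson correlation among a feature
  subset; edges only where |r| > 0.5, drawn with thickness 10·|r| − 5.
* Five filter/wrapper rankers: correlation with the target (point-biserial),
  Welch's t, K-Best (ANOVA F), recursive feature elimination with an
  L2 logistic classifier, and ReliefF.
* :func:`cwf_combine` — consensus of the five: features in the top-20 of at
  least three methods, ordered by their mean within-top-20 rank.

All rankings are :class:`ImportanceRanking` objects; scores are sorted
descending (for CWF the stored score is the mean rank and *lower* is
better, reflected in the ordering).  Ties everywhere break
lexicographically by feature name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier


@dataclass
class RFConfig:
    """Random-forest configuration for the OOB importance analysis."""

    n_trees: int = 700
    criterion: str = "gini"
    max_features_per_tree: int = 10
    max_depth: int | None = None  # unlimited
    class_weight: str = "balanced"  # inverse class frequency
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.max_features_per_tree <= n_features:
            raise ValueError("max_features_per_tree out of range")


@dataclass
class ImportanceRanking:
    """An ordered list of (feature, score) pairs, most important first."""

    method: str
    entries: list[tuple[str, float]]
    normalized: bool = False
    ascending: bool = False  # True when lower score = more important (CWF)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.method}: duplicate feature names in ranking")

    @property
    def features(self) -> list[str]:
        return [n for n, _ in self.entries]

    def top(self, k: int = 20) -> list[str]:
        return self.features[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.entries) + 1),
             "feature": self.features,
             "score": [s for _, s in self.entries]}
        )


def _sorted_entries(names, scores, ascending: bool = False) -> list[tuple[str, float]]:
    """Sort by score (desc by default), ties lexicographic by name."""
    sign = 1.0 if ascending else -1.0
    order = sorted(range(len(names)), key=lambda i: (sign * scores[i], names[i]))
    return [(names[i], float(scores[i])) for i in order]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _as_labels(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    return (y == classes[1]).astype(int)


def _constant_columns(Xm: np.ndarray) -> np.ndarray:
    """Exactly constant features (score 0 in every univariate ranker).

    The max==min test avoids the float artifact where n identical values
    yield a variance of ~1e-16 through mean round-off, which would turn a
    0/0 statistic into an arbitrary finite one.
    """
    return Xm.max(axis=0) == Xm.min(axis=0)


# ---------------------------------------------------------------------------
# OOB random-forest importance

def oob_importance(X, y, cfg: RFConfig | None = None) -> ImportanceRanking:
    """Out-of-bag permutation importance of a random-subspace forest.

    Each of the ``n_trees`` trees is fit on a bootstrap resample restricted
    to ``max_features_per_tree`` randomly chosen features.  Its out-of-bag
    samples give a baseline accuracy; permuting one feature column of the
    OOB block and re-predicting measures that feature's contribution as the
    accuracy decrease.  Per-feature importance is the mean decrease over
    the trees whose subspace included the feature (zero if none did),
    normalized so the maximum score is 1.
    """
    cfg = cfg or RFConfig()
    Xm, names = _as_matrix(X)
    yb = _as_labels(y)
    n, p = Xm.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    cfg.validate(p)
    if np.isnan(Xm).any():
        raise ValueError("missing values present; impute before ranking")

    rng = np.random.default_rng(cfg.seed)
    drops = np.zeros(p)
    used = np.zeros(p)
    for _ in range(cfg.n_trees):
        feats = rng.choice(p, size=cfg.max_features_per_tree, replace=False)
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or np.unique(yb[boot]).size < 2:
            continue
        tree = DecisionTreeClassifier(
            criterion=cfg.criterion,
            max_depth=cfg.max_depth,
            class_weight=cfg.class_weight,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xm[np.ix_(boot, feats)], yb[boot])
        X_oob = Xm[np.ix_(oob, feats)]
        y_oob = yb[oob]
        base_acc = float(np.mean(tree.predict(X_oob) == y_oob))
        for j, f in enumerate(feats):
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            acc = float(np.mean(tree.predict(X_perm) == y_oob))
            drops[f] += base_acc - acc
            used[f] += 1
    scores = np.divide(drops, used, out=np.zeros(p), where=used > 0)
    m = scores.max()
    if m > 0:
        scores = scores / m
    return ImportanceRanking("OOB", _sorted_entries(names, scores), normalized=m > 0)


# ---------------------------------------------------------------------------
# correlation graph

def correlation_graph(X, features: list[str] | None = None, threshold: float = 0.5) -> nx.Graph:
    """Pearson correlation graph over a feature subset.

    Nodes are features (zero-variance ones are dropped with a warning);
    an edge joins two features whose absolute correlation strictly exceeds
    ``threshold``, with attributes ``abs_r`` and ``thickness = 10|r| − 5``.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(_as_matrix(X)[0], columns=_as_matrix(X)[1])
    if features is not None:
        X = X[list(features)]
    if len(X) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    col_range = X.max() - X.min()
    dead = [c for c in X.columns if col_range[c] == 0]
    if dead:
        warnings.warn(f"zero-variance features excluded from graph: {dead}")
        X = X.drop(columns=dead)
    g = nx.Graph()
    g.add_nodes_from(X.columns)
    corr = X.corr().to_numpy()
    cols = list(X.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            # round away float dust so an exactly-threshold correlation
            # (up to accumulation error) is excluded as the rule requires
            r = round(abs(corr[i, j]), 12)
            if r > threshold:
                g.add_edge(cols[i], cols[j], abs_r=float(r), thickness=float(10 * r - 5))
    return g


def edge_thickness(abs_r: float) -> float:
    """Line thickness used when drawing a correlation edge: 10·|r| − 5."""
    return 10.0 * abs_r - 5.0


# ---------------------------------------------------------------------------
# filter / wrapper rankers

def rank_by_target_correlation(X, y) -> ImportanceRanking:
    """Rank by |point-biserial correlation| with the binary response."""
    Xm, names = _as_matrix(X)
    yb = _as_labels(y)
    yc = yb - yb.mean()
    xc = Xm - Xm.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, np.abs(xc.T @ yc) / denom, 0.0)
    r[_constant_columns(Xm)] = 0.0
    return ImportanceRanking("corr_target", _sorted_entries(names, r))


def rank_by_welch_t(X, y) -> ImportanceRanking:
    """Rank by |Welch's t| (unequal-variance two-sample statistic)."""
    Xm, names = _as_matrix(X)
    yb = _as_labels(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, _ = stats.ttest_ind(Xm[yb == 1], Xm[yb == 0], equal_var=False, axis=0)
    t = np.nan_to_num(np.abs(t), nan=0.0)
    t[_constant_columns(Xm)] = 0.0
    return ImportanceRanking("welch_t", _sorted_entries(names, t))


def rank_by_kbest(X, y) -> ImportanceRanking:
    """Rank by the univariate ANOVA F score (the K-Best criterion)."""
    Xm, names = _as_matrix(X)
    yb = _as_labels(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, _ = f_classif(Xm, yb)
    f = np.nan_to_num(f, nan=0.0)
    f[_constant_columns(Xm)] = 0.0
    return ImportanceRanking("kbest_f", _sorted_entries(names, f))


def rank_by_rfe(X, y, C: float = 1.0) -> ImportanceRanking:
    """Recursive feature elimination with an L2 logistic classifier.

    Features are z-scored; each round fits the classifier on the surviving
    set and eliminates the feature with the smallest |coefficient| (ties:
    the lexicographically greatest name goes first).  The score is the
    elimination round, so the last survivor ranks first.
    """
    Xm, names = _as_matrix(X)
    yb = _as_labels(y)
    sd = Xm.std(axis=0, ddof=0)
    mu = Xm.mean(axis=0)
    Z = (Xm - mu) / np.where(sd > 0, sd, 1.0)
    Z[:, _constant_columns(Xm)] = 0.0
    alive = list(range(Xm.shape[1]))
    elim_round = np.zeros(Xm.shape[1])
    rounds = 0
    while len(alive) > 1:
        clf = LogisticRegression(C=C, max_iter=1000)  # l2 penalty (default)
        clf.fit(Z[:, alive], yb)
        coefs = np.abs(clf.coef_[0])
        lo = coefs.min()
        tied = [i for i in range(len(alive)) if coefs[i] <= lo + 1e-12 * max(lo, 1.0)]
        worst = max(tied, key=lambda i: names[alive[i]])
        rounds += 1
        elim_round[alive[worst]] = rounds
        del alive[worst]
    elim_round[alive[0]] = rounds + 1
    return ImportanceRanking("rfe", _sorted_entries(names, elim_round))


def relief_weights(X, y, k_neighbors: int = 10) -> np.ndarray:
    """ReliefF feature weights.

    Features are min-max scaled; for every sample the ``k`` nearest hits
    (same class) and ``k`` nearest misses (other class) under Euclidean
    distance contribute ``mean|diff| to misses − mean|diff| to hits`` per
    feature; weights are averaged over samples.  With fewer than ``k``
    neighbours available, all available ones are used; an empty neighbour
    set contributes zero.
    """
    Xm, _ = _as_matrix(X)
    yb = _as_labels(y)
    n, p = Xm.shape
    rng_range = Xm.max(axis=0) - Xm.min(axis=0)
    scale = np.where(rng_range > 0, rng_range, 1.0)
    Z = (Xm - Xm.min(axis=0)) / scale
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(p)
    for i in range(n):
        for target, sign in ((yb[i], -1.0), (1 - yb[i], 1.0)):
            idx = np.where(yb == target)[0]
            idx = idx[idx != i]
            if idx.size == 0:
                continue
            k = min(k_neighbors, idx.size)
            nearest = idx[np.argsort(d2[i, idx], kind="stable")[:k]]
            diffs = np.abs(Z[nearest] - Z[i]).mean(axis=0)
            w += sign * diffs
    return w / n


def rank_by_relief(X, y, k_neighbors: int = 10) -> ImportanceRanking:
    """Rank by ReliefF weight, descending."""
    _, names = _as_matrix(X)
    w = relief_weights(X, y, k_neighbors)
    return ImportanceRanking("relief", _sorted_entries(names, w))


FILTER_WRAPPER_METHODS = (
    rank_by_target_correlation,
    rank_by_welch_t,
    rank_by_kbest,
    rank_by_rfe,
    rank_by_relief,
)


def run_filter_wrapper_rankings(X, y) -> list[ImportanceRanking]:
    """Run the five filter/wrapper rankers in their canonical order."""
    return [m(X, y) for m in FILTER_WRAPPER_METHODS]


# ---------------------------------------------------------------------------
# CWF combination and summaries

def cwf_combine(
    rankings: list[ImportanceRanking], top_k: int = 20, min_methods: int = 3
) -> ImportanceRanking:
    """Consensus of the five filter/wrapper rankings.

    A feature is eligible when it appears in the top-``top_k`` of at least
    ``min_methods`` rankings; its score is the mean of its (1-based) ranks
    within the top-``top_k`` lists where it appears.  Output is ordered by
    ascending mean rank, ties lexicographic.
    """
    if len(rankings) != 5:
        raise ValueError("cwf_combine expects exactly 5 rankings")
    appearances: dict[str, list[int]] = {}
    for rk in rankings:
        for pos, name in enumerate(rk.top(top_k), start=1):
            appearances.setdefault(name, []).append(pos)
    eligible = {n: rs for n, rs in appearances.items() if len(rs) >= min_methods}
    names = list(eligible)
    scores = [float(np.mean(eligible[n])) for n in names]
    return ImportanceRanking("CWF", _sorted_entries(names, scores, ascending=True), ascending=True)


def view_census(features: list[str]) -> dict[str, int]:
    """Count features per echocardiographic view (QRS/LVEF under ``none``)."""
    from .features import feature_view

    counts = {"4ch": 0, "3ch": 0, "2ch": 0, "none": 0}
    for name in features:
        vw = feature_view(name)
        counts[vw if vw is not None else "none"] += 1
    return counts


def ranking_overlap(a: ImportanceRanking | list[str], b: ImportanceRanking | list[str], top_k: int = 20) -> int:
    """Number of features shared by the two top-``top_k`` lists."""
    ta = a.top(top_k) if isinstance(a, ImportanceRanking) else list(a)[:top_k]
    tb = b.top(top_k) if isinstance(b, ImportanceRanking) else list(b)[:top_k]
    return len(set(ta) & set(tb))


def impute_median(X: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing feature values (undefined peak-time statistics)."""
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        import logging

        logging.getLogger(__name__).info("median-imputing %d missing values", n_missing)
        X = X.fillna(X.median(numeric_only=True))
    return X
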