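"""Alternative dynamic-regime detection and treatment-association tests.

Replicate time series (dissolved oxygen or total biomass) are compared with
a dynamic time warping (DTW) distance, clustered hierarchically with the
Ward criterion, and cut into k = 2 candidate regimes.  Cluster membership
is then related to the experimental gas-exchange treatment with a logistic
likelihood-ratio test, and the nonlinearity/hysteresis response metrics are
compared across treatments (and clusters) with ANOVA / additive ANCOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "series_matrix",
    "dtw_distance",
    "dtw_matrix",
    "ward_cluster",
    "DTWWardClustering",
    "combine_regimes",
    "AssociationTest",
    "association_lrt",
    "metric_anova",
]


def series_matrix(table: pd.DataFrame, variable: str):
    """Pivot a long-format experiment table into (ids, series matrix).

    One row per microcosm, columns ordered by sampling day; microcosm order
    follows first appearance in the table.
    """
    ids = table["microcosm_id"].drop_duplicates().to_list()
    wide = table.pivot(index="microcosm_id", columns="day", values=variable)
    wide = wide.loc[ids].sort_index(axis=1)
    if wide.isna().any().any():
        raise ValueError("unbalanced sampling schedule across microcosms")
    return ids, wide.to_numpy()


def _zscale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def dtw_distance(x, y, window: int | None = None) -> float:
    """Classic dynamic time warping alignment cost between two series.

    Unconstrained symmetric step pattern with absolute local cost:
    D(i,j) = |x_i - y_j| + min(D(i-1,j), D(i,j-1), D(i-1,j-1)).  A
    Sakoe-Chiba band of half-width ``window`` can optionally constrain the
    warping path.  DTW is not a metric (no triangle inequality), but it is
    symmetric and zero on identical series.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("series must be nonempty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    n, m = len(x), len(y)
    big = np.inf
    prev = np.full(m + 1, big)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, big)
        cost = np.abs(x[i - 1] - y)  # local cost row
        lo, hi = 1, m
        if window is not None:
            lo = max(1, i - window)
            hi = min(m, i + window)
        for j in range(lo, hi + 1):
            cur[j] = cost[j - 1] + min(prev[j], cur[j - 1], prev[j - 1])
        prev = cur
    return float(prev[m])


def dtw_matrix(
    series, normalize: bool = True, window: int | None = None
) -> np.ndarray:
    """Pairwise DTW distance matrix over a collection of series.

    With ``normalize=True`` (default) every series is standardized to mean
    zero and unit standard deviation first; a constant series standardizes
    to all-zeros.
    """
    arrs = [np.asarray(s, dtype=float).ravel() for s in series]
    if len(arrs) < 2:
        raise ValueError("need at least 2 series")
    if normalize:
        arrs = [_zscale(a) for a in arrs]
    n = len(arrs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(arrs[i], arrs[j], window=window)
    return D


def ward_cluster(distance_matrix: np.ndarray, k: int = 2, dialect: str = "d2"):
    """Agglomerative Ward clustering of a precomputed distance matrix.

    ``dialect='d2'`` (default) applies the Ward criterion to squared
    distances, the convention of modern implementations; ``'d1'`` applies
    it to the distances as given.  Returns (labels in 1..k, merge history).
    Ties are broken deterministically by the condensed-index order.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("invalid distance matrix")
    if k > n or k < 1:
        raise ValueError(f"cannot cut {n} series into {k} clusters")
    if dialect == "d2":
        cond = squareform(D, checks=False)
    elif dialect == "d1":
        cond = np.sqrt(squareform(D, checks=False))
    else:
        raise ValueError("dialect must be 'd2' or 'd1'")
    Z = linkage(cond, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


class DTWWardClustering(BaseEstimator, ClusterMixin):
    """Dynamic-regime detection: DTW distances + Ward hierarchical clustering.

    Parameters
    ----------
    k : int
        Number of clusters cut from the dendrogram (two dynamic regimes by
        default).
    normalize : bool
        Standardize each series (mean 0, sd 1) before DTW.
    window : int or None
        Optional Sakoe-Chiba band half-width; unconstrained by default.
    dialect : {"d2", "d1"}
        Ward-on-squared-distances (modern convention) or plain Ward.
    anchor : {"high", "low", None}
        Cluster-identity anchoring: cluster 1 is the cluster whose member
        series have the higher (resp. lower) mean level, making labels
        reproducible across runs.  ``None`` keeps the dendrogram order.

    Attributes
    ----------
    distance_matrix_ : (n, n) DTW distances
    linkage_ : scipy merge history
    labels_ : cluster labels in {1, .., k}
    """

    def __init__(
        self,
        k: int = 2,
        normalize: bool = True,
        window: int | None = None,
        dialect: str = "d2",
        anchor: str | None = "high",
    ):
        self.k = k
        self.normalize = normalize
        self.window = window
        self.dialect = dialect
        self.anchor = anchor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_series, n_timepoints)")
        self.distance_matrix_ = dtw_matrix(
            X, normalize=self.normalize, window=self.window
        )
        raw, self.linkage_ = ward_cluster(
            self.distance_matrix_, k=self.k, dialect=self.dialect
        )
        if self.anchor is not None and self.k == 2:
            means = np.array(
                [X[raw == lab].mean() if np.any(raw == lab) else np.nan for lab in (1, 2)]
            )
            # cluster "1" = majority high-level (or low-level) dynamics
            first = int(np.nanargmax(means)) + 1 if self.anchor == "high" else (
                int(np.nanargmin(means)) + 1
            )
            self.labels_ = np.where(raw == first, 1, 2)
        else:
            self.labels_ = raw
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def combine_regimes(labels_do, labels_biomass) -> np.ndarray:
    """Combined regime code from the two per-variable clusterings.

    With cluster 1 anchored to the majority high-DO (resp. low-biomass)
    dynamics: A = (1, 1), B = (2, 1), C = (2, 2); the remaining
    combination (1, 2) is reported as 'other'.
    """
    ldo = np.asarray(labels_do)
    lbm = np.asarray(labels_biomass)
    if ldo.shape != lbm.shape:
        raise ValueError("label arrays must have equal length")
    if not set(np.unique(ldo)) <= {1, 2} or not set(np.unique(lbm)) <= {1, 2}:
        raise ValueError("labels must be in {1, 2}")
    code = {(1, 1): "A", (2, 1): "B", (2, 2): "C", (1, 2): "other"}
    return np.array([code[(int(a), int(b))] for a, b in zip(ldo, lbm)])


@dataclass(frozen=True)
class AssociationTest:
    """Likelihood-ratio test of cluster membership against treatment."""

    deviance: float
    df: int
    p_value: float


def association_lrt(outcome, treatment) -> AssociationTest:
    """Logistic-regression likelihood-ratio test for a categorical predictor.

    Because the only predictor is the treatment factor, the fitted logistic
    regression is saturated by group and its maximized Bernoulli likelihood
    has the closed form with group-proportion estimates (0*log 0 = 0);
    deviance = 2 [l_group - l_null], df = (number of levels - 1), p-value
    from the chi-square distribution.
    """
    y = np.asarray(outcome)
    g = np.asarray(treatment)
    if y.shape != g.shape:
        raise ValueError("outcome and treatment must have equal length")
    classes = np.unique(y)
    if len(classes) > 2:
        raise ValueError("outcome must be binary")
    yb = (y == classes[-1]).astype(float)
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 treatment levels")

    def bern_ll(k: float, n: float) -> float:
        ll = 0.0
        if 0 < k:
            ll += k * np.log(k / n)
        if k < n:
            ll += (n - k) * np.log((n - k) / n)
        return ll

    n = len(yb)
    ll_null = bern_ll(yb.sum(), n)
    ll_group = sum(bern_ll(yb[g == lv].sum(), (g == lv).sum()) for lv in levels)
    dev = max(2.0 * (ll_group - ll_null), 0.0)
    df = len(levels) - 1
    return AssociationTest(
        deviance=float(dev), df=int(df), p_value=float(chi2.sf(dev, df))
    )


def metric_anova(
    values,
    treatment,
    cluster=None,
    interaction: bool = False,
) -> pd.DataFrame:
    """ANOVA / additive ANCOVA of a response metric on categorical factors.

    One-way ANOVA on the treatment factor; adding ``cluster`` gives the
    additive two-factor linear model with F-tests from nested
    residual-sum-of-squares comparisons (each factor adjusted for the
    other); ``interaction=True`` additionally fits and tests the
    treatment x cluster interaction.  Returns the statsmodels ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "trt": np.asarray(treatment)})
    if df["trt"].nunique() < 2:
        raise ValueError("need >= 2 treatment levels")
    rhs = "C(trt)"
    if cluster is not None:
        df["clus"] = np.asarray(cluster)
        rhs += " + C(clus)"
        if interaction:
            rhs += " + C(trt):C(clus)"
    n_params = sum(df[c].nunique() - 1 for c in df.columns if c != "y") + 1
    if len(df) <= n_params:
        raise ValueError("too few observations for the requested design")
    model = smf.ols(f"y ~ {rhs}", data=df).fit()
    if cluster is not None and np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("degenerate design: treatment and cluster factors are aliased")
    typ = 2 if cluster is not None else 1
    table = anova_lm(model, typ=typ)
    return table
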