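"""Statistical structure of the mortuary record (binary grave-good matrices).

Covers the chain the funerary analysis uses: Jaccard distances between
individuals' grave-good kits, complete-linkage clustering, goods-by-group
chi-square, one-level AMOVA with permutation Phi_ST on the distance matrix,
correspondence analysis, Random-Forest variable importance with out-of-bag
error, and stepwise VIF collinearity pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .records import BinaryArtifactMatrix

__all__ = [
    "jaccard_matrix",
    "complete_linkage",
    "goods_by_group_chisq",
    "AmovaResult",
    "amova",
    "CaResult",
    "CorrespondenceAnalysis",
    "correspondence_analysis",
    "RfResult",
    "random_forest_importance",
    "VIFSelector",
    "vif_stepwise",
]


def _presence_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, BinaryArtifactMatrix):
        return matrix.presence
    return pd.DataFrame(matrix)


def jaccard_matrix(matrix) -> pd.DataFrame:
    """Pairwise Jaccard distances between individuals' grave-good sets.

    d(i, j) = 1 - |intersection| / |union| over goods; two individuals with
    no goods at all are at distance 0 by convention.
    """
    df = _presence_frame(matrix)
    X = df.to_numpy(dtype=float)
    inter = X @ X.T
    totals = X.sum(axis=1)
    union = totals[:, None] + totals[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def complete_linkage(distance_matrix) -> np.ndarray:
    """Farthest-neighbour agglomeration; merge heights are non-decreasing."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.shape[0] < 2:
        raise ValueError("need at least two individuals to cluster")
    return linkage(squareform(D, checks=False), method="complete")


def goods_by_group_chisq(
    matrix: BinaryArtifactMatrix, grouping: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square on the goods-type x group occurrence-count table.

    Each individual contributes one count per good possessed, so the table
    cell (good, group) is the number of members of the group buried with that
    good.  Goods never occurring in any retained group are dropped (with a
    warning) before computing df = (goods - 1) * (groups - 1).  Individuals
    with missing group labels are excluded.
    """
    grouping = grouping.reindex(matrix.presence.index)
    keep = grouping.notna()
    groups = grouping[keep]
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    table = matrix.presence[keep].groupby(groups).sum().T  # goods x groups
    zero = table.sum(axis=1) == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} goods with zero total count", stacklevel=2
        )
        table = table[~zero]
    obs = table.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p, table


@dataclass
class AmovaResult:
    phi_st: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    permutation_p: Optional[float]
    n_permutations: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _amova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return float(ss_total), float(ss_within)


def _phi_st(d2: np.ndarray, labels: np.ndarray) -> tuple:
    n = d2.shape[0]
    uniq, counts = np.unique(labels, return_counts=True)
    g = len(uniq)
    ss_total, ss_within = _amova_ss(d2, labels)
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (n - (counts**2).sum() / n) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    denom = sigma2_among + sigma2_within
    phi = sigma2_among / denom if denom != 0 else np.nan
    return phi, ss_among, ss_within, df_among, df_within, sigma2_among, sigma2_within


def amova(
    distance_matrix,
    grouping,
    n_permutations: int = 9999,
    seed: Optional[int] = None,
) -> AmovaResult:
    """One-level AMOVA on a symmetric distance matrix.

    Distances are squared inside the sums of squares (the molecular-variance
    convention), variance components use the weighted average group size n0,
    and Phi_ST = sigma2_among / (sigma2_among + sigma2_within), reported as
    computed (it may be negative for less-than-random structure).  The
    permutation p-value is (1 + #{Phi_perm >= Phi_obs}) / (1 + B) under
    random relabeling of individuals.

    Individuals with missing group labels are excluded first; single-member
    groups are allowed (they contribute zero within-group SS) with a warning.
    """
    D = (
        distance_matrix.to_numpy(dtype=float)
        if isinstance(distance_matrix, pd.DataFrame)
        else np.asarray(distance_matrix, dtype=float)
    )
    labels = np.asarray(pd.Series(grouping), dtype=object)
    keep = np.array([not pd.isna(x) for x in labels])
    D = D[np.ix_(keep, keep)]
    labels = labels[keep]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups with labels")
    if (counts == 1).any():
        warnings.warn("group(s) of size 1 contribute no within-group SS", stacklevel=2)
    d2 = D**2
    phi, ss_a, ss_w, df_a, df_w, s2_a, s2_w = _phi_st(d2, labels)
    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            if _phi_st(d2, perm)[0] >= phi:
                hits += 1
        p = (1.0 + hits) / (1.0 + n_permutations)
    return AmovaResult(
        phi_st=float(phi),
        ss_among=ss_a,
        ss_within=ss_w,
        df_among=df_a,
        df_within=df_w,
        sigma2_among=float(s2_a),
        sigma2_within=float(s2_w),
        permutation_p=p,
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class CaResult:
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertia_shares: np.ndarray
    total_inertia: float


class CorrespondenceAnalysis(BaseEstimator, TransformerMixin):
    """Correspondence analysis of a non-negative contingency table.

    Singular value decomposition of the standardized (Pearson) residual
    matrix; principal coordinates scale the singular vectors by the singular
    values, and the total inertia equals chi-square / N, partitioned by axis.
    All-zero rows or columns are dropped with a warning.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        df = pd.DataFrame(X)
        if (df.to_numpy() < 0).any():
            raise ValueError("contingency table must be non-negative")
        zero_r = df.sum(axis=1) == 0
        zero_c = df.sum(axis=0) == 0
        if zero_r.any() or zero_c.any():
            warnings.warn(
                f"dropping {int(zero_r.sum())} all-zero rows and "
                f"{int(zero_c.sum())} all-zero columns",
                stacklevel=2,
            )
            df = df.loc[~zero_r, ~zero_c]
        N = df.to_numpy(dtype=float)
        total = N.sum()
        if total <= 0:
            raise ValueError("grand total must be positive")
        P = N / total
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        keep = sv > 1e-12
        U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
        dims = min(self.n_components, len(sv))
        rows = (U[:, :dims] * sv[:dims]) / np.sqrt(r)[:, None]
        cols = (Vt[:dims].T * sv[:dims]) / np.sqrt(c)[:, None]
        axes = [f"axis{i + 1}" for i in range(dims)]
        inertia = sv**2
        self.result_ = CaResult(
            row_coords=pd.DataFrame(rows, index=df.index, columns=axes),
            col_coords=pd.DataFrame(cols, index=df.columns, columns=axes),
            inertia_shares=(
                inertia[:dims] / inertia.sum() if inertia.sum() > 0 else inertia[:dims]
            ),
            total_inertia=float(inertia.sum()),
        )
        return self

    def transform(self, X=None):
        check_is_fitted(self, "result_")
        return self.result_.row_coords.to_numpy()


def correspondence_analysis(table, n_components: int = 2) -> CaResult:
    """Functional wrapper over :class:`CorrespondenceAnalysis`."""
    return CorrespondenceAnalysis(n_components=n_components).fit(table).result_


@dataclass
class RfResult:
    importances: pd.Series  # mean Gini-impurity decrease per variable
    oob_error: float
    confusion: pd.DataFrame  # out-of-bag confusion matrix (rows = true class)
    params: dict = field(default_factory=dict)


def random_forest_importance(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    max_features: "str | int" = "sqrt",
    seed: Optional[int] = None,
) -> RfResult:
    """Random-Forest Gini importances with out-of-bag error.

    Classification trees are grown on bootstrap samples; each split considers
    a random predictor subset (default ~sqrt of the predictor count).  The
    out-of-bag error and confusion matrix come from votes of trees that did
    not sample each individual; importance is the forest-averaged decrease in
    Gini impurity attributable to splits on each variable.
    """
    labels = pd.Series(labels).reindex(features.index)
    keep = labels.notna()
    X = features[keep]
    y = labels[keep].astype(str)
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError("need at least two classes")
    if (class_counts < 2).any():
        small = class_counts[class_counts < 2].index.tolist()
        raise ValueError(f"classes with a single member (OOB undefined): {small}")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
    ).fit(X.to_numpy(), y.to_numpy())
    oob_pred = rf.classes_[np.argmax(rf.oob_decision_function_, axis=1)]
    classes = list(rf.classes_)
    conf = pd.crosstab(
        pd.Categorical(y, categories=classes),
        pd.Categorical(oob_pred, categories=classes),
        dropna=False,
    )
    conf.index = classes
    conf.columns = classes
    return RfResult(
        importances=pd.Series(rf.feature_importances_, index=X.columns).sort_values(
            ascending=False
        ),
        oob_error=float(1.0 - rf.oob_score_),
        confusion=conf,
        params={"n_trees": n_trees, "max_features": str(max_features), "seed": seed},
    )


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) of each column regressed on the others
    (with intercept); perfect collinearity maps to +inf."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    exog = np.hstack([np.ones((X.shape[0], 1)), X])
    out = np.empty(X.shape[1])
    with np.errstate(divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for j in range(X.shape[1]):
                v = variance_inflation_factor(exog, j + 1)
                out[j] = np.inf if (not np.isfinite(v) or v > 1e12) else v
    return out


class VIFSelector(BaseEstimator, TransformerMixin):
    """Stepwise variance-inflation-factor variable selection.

    Constant columns are removed first, then the maximum-VIF variable is
    dropped repeatedly (ties broken by column order) until every remaining
    VIF is at or below the threshold.  Perfectly collinear variables have
    infinite VIF and go first.
    """

    def __init__(self, threshold: float = 5.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        df = pd.DataFrame(X).astype(float)
        if df.shape[1] < 2:
            raise ValueError("need at least two variables")
        removed = [c for c in df.columns if df[c].nunique() <= 1]
        retained = [c for c in df.columns if c not in removed]
        while len(retained) > 1:
            vifs = _vifs(df[retained].to_numpy())
            worst = int(np.argmax(vifs))
            if vifs[worst] <= self.threshold:
                break
            removed.append(retained.pop(worst))
        final = (
            _vifs(df[retained].to_numpy()) if len(retained) > 1 else np.ones(len(retained))
        )
        self.retained_ = retained
        self.removed_ = removed
        self.vifs_ = pd.Series(final, index=retained)
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        return pd.DataFrame(X)[self.retained_]


def vif_stepwise(features, threshold: float = 5.0):
    """Functional wrapper over :class:`VIFSelector`.

    Returns (retained columns, removed columns, final VIFs).
    """
    sel = VIFSelector(threshold=threshold).fit(features)
    return sel.retained_, sel.removed_, sel.vifs_
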