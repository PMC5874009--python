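"""Dental non-metric biodistance: dichotomization, screening, and MMD.

The Mean Measure of Divergence (MMD) between two groups over r dichotomized
traits is

    MMD = (1/r) * sum_i [ (theta_Ai - theta_Bi)^2 - (1/n_Ai + 1/n_Bi) ]

where theta is a variance-stabilizing angular transform of the trait
frequency k/n and the subtracted term removes the sampling-variance bias, so
MMD may legitimately be negative for very similar groups.  Its standard
deviation depends on sample sizes only:

    SD = sqrt( (2/r^2) * sum_i (1/n_Ai + 1/n_Bi)^2 )

and a pairwise divergence is conventionally called significant when
MMD > 2*SD (roughly p < 0.025).

The default angular transform is the symmetric Freeman-Tukey form

    theta(k, n) = 1/2 * [ asin(1 - 2k/(n+1)) + asin(1 - 2(k+1)/(n+1)) ]

with the 1/n correction; an asymmetric variant and the Anscombe transform,
and the n+0.5 small-sample correction, are available behind flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .records import GroupTraitFrequencies, TraitDefinition

__all__ = [
    "counts_from_percentages",
    "dichotomize",
    "correlation_screen",
    "drop_sparse_traits",
    "ft_theta",
    "mmd_pair",
    "mmd_matrix",
    "MmdMatrix",
    "ClassicalMDS",
    "classical_mds",
    "ward_dendrogram",
    "clamp_distances",
]


def counts_from_percentages(percent: float, n: int) -> int:
    """Recover the presence count k from a printed percentage and sample size.

    k = round(percent * n / 100) to the nearest integer.  A warning is issued
    when the recovered count does not reproduce the percentage within printing
    precision (0.05), which flags an inconsistent source table.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent {percent} outside [0, 100]")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = int(round(percent * n / 100.0))
    if abs(100.0 * k / n - percent) > 0.05:
        warnings.warn(
            f"count {k}/{n} reproduces {100.0 * k / n:.2f}%, printed {percent}%",
            stacklevel=2,
        )
    return k


def dichotomize(
    scores: pd.DataFrame, definitions: Iterable[TraitDefinition]
) -> pd.DataFrame:
    """Convert an individual x trait table of ASUDAS grades to presence {0,1}.

    ``scores`` holds one effective grade per individual-trait (left side
    preferred, antimere already substituted); missing grades stay missing.
    """
    defs = {d.name: d for d in definitions}
    missing = [t for t in scores.columns if t not in defs]
    if missing:
        raise ValueError(f"traits without definitions: {missing}")
    out = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for trait in scores.columns:
        d = defs[trait]
        for ind, grade in scores[trait].items():
            if pd.isna(grade):
                continue
            try:
                out.loc[ind, trait] = float(d.is_present(grade))
            except ValueError as exc:
                raise ValueError(f"individual {ind!r}: {exc}") from exc
    return out


def drop_sparse_traits(
    presence: pd.DataFrame, min_observations: int = 5
) -> tuple[pd.DataFrame, list[str]]:
    """Drop traits scored in fewer than ``min_observations`` individuals."""
    n_obs = presence.notna().sum(axis=0)
    dropped = list(n_obs.index[n_obs < min_observations])
    return presence.drop(columns=dropped), dropped


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    """Signed phi coefficient of two binary vectors (sqrt(chi2/N) with the
    sign of the 2x2 table determinant)."""
    a = float(np.sum((x == 1) & (y == 1)))
    b = float(np.sum((x == 1) & (y == 0)))
    c = float(np.sum((x == 0) & (y == 1)))
    d = float(np.sum((x == 0) & (y == 0)))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return (a * d - b * c) / np.sqrt(denom)


def correlation_screen(
    presence: pd.DataFrame, r_threshold: float = 0.5
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Iteratively drop traits involved in |phi| > threshold associations.

    Pairwise phi is computed on complete observation pairs.  At each step the
    trait participating in the most above-threshold pairs is removed (ties
    broken toward the trait with fewer observations); the loop ends when no
    pair exceeds the threshold.  Traits with no pairwise overlap with any
    other trait are retained with a warning.
    """
    traits = list(presence.columns)
    if len(traits) < 2:
        raise ValueError("need at least two traits to screen")
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    overlap = pd.DataFrame(0, index=traits, columns=traits)
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1 :]:
            both = presence[[t1, t2]].dropna()
            overlap.loc[t1, t2] = overlap.loc[t2, t1] = len(both)
            val = _phi(both[t1].to_numpy(), both[t2].to_numpy()) if len(both) else np.nan
            r.loc[t1, t2] = r.loc[t2, t1] = val

    for t in traits:
        others = [u for u in traits if u != t]
        if overlap.loc[t, others].max() == 0:
            warnings.warn(f"trait {t!r} has no pairwise overlap; retained", stacklevel=2)

    retained = list(traits)
    removed = []
    n_obs = presence.notna().sum(axis=0)
    while True:
        sub = r.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        counts = (sub > r_threshold).sum(axis=1)
        if counts.max() == 0:
            break
        worst = counts[counts == counts.max()].index
        victim = min(worst, key=lambda t: (n_obs[t], retained.index(t)))
        retained.remove(victim)
        removed.append(victim)
    return retained, removed, r


_VARIANTS = ("freeman_tukey", "asymmetric", "anscombe")


def ft_theta(k, n, variant: str = "freeman_tukey"):
    """Angular transform of a trait frequency k/n, in radians.

    Strictly decreasing in k at fixed n: theta(0, n) is near +pi/2 and
    theta(n, n) near -pi/2.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(k > n) or np.any(n < 1):
        raise ValueError("require 0 <= k <= n and n >= 1")
    if variant == "freeman_tukey":
        return 0.5 * (
            np.arcsin(1 - 2 * k / (n + 1)) + np.arcsin(1 - 2 * (k + 1) / (n + 1))
        )
    if variant == "asymmetric":
        return 0.5 * (np.arcsin(1 - 2 * k / n) + np.arcsin(1 - 2 * (k + 1) / (n + 1)))
    if variant == "anscombe":
        return np.arcsin(1 - 2 * (k + 3.0 / 8.0) / (n + 3.0 / 4.0))
    raise ValueError(f"unknown variant {variant!r}; choose from {_VARIANTS}")


def _correction(n_a: float, n_b: float, correction: str) -> float:
    if correction == "n":
        return 1.0 / n_a + 1.0 / n_b
    if correction == "n_plus_half":
        return 1.0 / (n_a + 0.5) + 1.0 / (n_b + 0.5)
    raise ValueError(f"unknown correction {correction!r}")


def mmd_pair(
    freq_a: GroupTraitFrequencies,
    freq_b: GroupTraitFrequencies,
    traits: Sequence[str],
    variant: str = "freeman_tukey",
    correction: str = "n",
) -> tuple[float, float]:
    """MMD and its SD between two groups over the given traits."""
    missing = [
        t for t in traits if t not in freq_a.counts or t not in freq_b.counts
    ]
    if missing:
        raise ValueError(
            f"traits missing in {freq_a.group!r} or {freq_b.group!r}: {missing}"
        )
    r = len(traits)
    if r == 0:
        raise ValueError("empty trait list")
    total = 0.0
    var = 0.0
    for t in traits:
        k_a, n_a = freq_a.counts[t]
        k_b, n_b = freq_b.counts[t]
        th_a = float(ft_theta(k_a, n_a, variant))
        th_b = float(ft_theta(k_b, n_b, variant))
        corr = _correction(n_a, n_b, correction)
        total += (th_a - th_b) ** 2 - corr
        var += corr**2
    return total / r, float(np.sqrt(2.0 * var / r**2))


@dataclass
class MmdMatrix:
    """Symmetric MMD matrix with SDs and MMD > 2*SD significance flags."""

    groups: list
    mmd: pd.DataFrame
    sd: pd.DataFrame
    significant: pd.DataFrame

    def to_table5_layout(self) -> pd.DataFrame:
        """MMD in the lower triangle, SD in the upper, empty diagonal."""
        out = self.mmd.where(np.tri(len(self.groups), k=-1, dtype=bool))
        upper = self.sd.where(~np.tri(len(self.groups), k=0, dtype=bool))
        return out.combine_first(upper)


def mmd_matrix(
    groups: Sequence[GroupTraitFrequencies],
    traits: Sequence[str],
    variant: str = "freeman_tukey",
    correction: str = "n",
) -> MmdMatrix:
    """All pairwise MMDs.  Diagonal reported as 0 by convention."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = [g.group for g in groups]
    n = len(labels)
    mmd = np.zeros((n, n))
    sd = np.zeros((n, n))
    sig = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            m, s = mmd_pair(groups[i], groups[j], traits, variant, correction)
            mmd[i, j] = mmd[j, i] = m
            sd[i, j] = sd[j, i] = s
            sig[i, j] = sig[j, i] = m > 2 * s
    return MmdMatrix(
        groups=labels,
        mmd=pd.DataFrame(mmd, index=labels, columns=labels),
        sd=pd.DataFrame(sd, index=labels, columns=labels),
        significant=pd.DataFrame(sig, index=labels, columns=labels),
    )


def clamp_distances(matrix: "pd.DataFrame | np.ndarray") -> np.ndarray:
    """Clamp negative dissimilarities to 0 (for ordination/clustering input).

    Reported MMD matrices keep their negative entries; only the geometric
    methods need a proper dissimilarity.
    """
    arr = np.asarray(matrix, dtype=float).copy()
    arr[arr < 0] = 0.0
    np.fill_diagonal(arr, 0.0)
    return arr


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared dissimilarity matrix, eigendecomposes, and
    embeds on the leading positive-eigenvalue axes.  Negative input entries
    (possible for MMD) are clamped to zero first.

    Attributes
    ----------
    embedding_ : (n, dims) array of principal coordinates
    eigenvalues_ : all eigenvalues, descending
    explained_inertia_ : per-retained-axis share of the positive eigenvalue sum
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        D = clamp_distances(X)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
            raise ValueError("need a symmetric dissimilarity matrix")
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        pos = int(np.sum(eigval > 1e-12))
        dims = self.n_components
        if dims > pos:
            warnings.warn(
                f"only {pos} positive eigenvalues; reducing dims from {dims}",
                stacklevel=2,
            )
            dims = max(pos, 1)
        coords = eigvec[:, :dims] * np.sqrt(np.maximum(eigval[:dims], 0.0))
        self.eigenvalues_ = eigval
        self.embedding_ = coords
        pos_sum = eigval[eigval > 0].sum()
        self.explained_inertia_ = (
            np.maximum(eigval[:dims], 0.0) / pos_sum if pos_sum > 0 else np.zeros(dims)
        )
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def classical_mds(distance_matrix, n_components: int = 2):
    """Functional wrapper over :class:`ClassicalMDS`; returns (coords, inertia shares)."""
    est = ClassicalMDS(n_components=n_components).fit(distance_matrix)
    return est.embedding_, est.explained_inertia_


def ward_dendrogram(distance_matrix) -> np.ndarray:
    """Ward linkage over a (possibly negative-entry) dissimilarity matrix.

    Returns a scipy linkage matrix; negatives are clamped first.  Pair with
    :func:`necropop.io.write_dendrogram` for Newick export.
    """
    D = clamp_distances(distance_matrix)
    if D.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    return linkage(squareform(D, checks=False), method="ward")
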