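"""Per-protein F-ratio screening, Ward clustering and PCA.

The retention rule screens each protein with a one-way between-group ANOVA
on its (normalized) per-run counts: F = model mean square / error mean
square on (g - 1, N - g) degrees of freedom, and a protein is retained when
F >= 2 and p <= 0.05. Retained profiles feed agglomerative hierarchical
clustering (Ward linkage, Euclidean metric) of samples and PCA of
condition-level aPSM profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from sklearn.decomposition import PCA

from .io import ConditionDesign, CountMatrix

F_MIN = 2.0
P_MAX = 0.05


@dataclass(frozen=True)
class ScreenResult:
    protein: str
    f_ratio: float
    p_value: float
    retained: bool


def _group_labels(
    design: ConditionDesign, grouping: str | list[str], run_ids: list[str]
) -> np.ndarray:
    meta = design.frame.set_index("run_id").loc[run_ids]
    if isinstance(grouping, str):
        if grouping == "condition":
            return design.condition_of().loc[run_ids].to_numpy()
        if grouping in meta.columns:
            return meta[grouping].to_numpy()
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = np.asarray(grouping)
    if len(labels) != len(run_ids):
        raise ValueError("grouping label list length mismatch")
    return labels


def f_screen(
    matrix: CountMatrix,
    design: ConditionDesign,
    grouping: str | list[str] = "condition",
    f_min: float = F_MIN,
    p_max: float = P_MAX,
) -> list[ScreenResult]:
    """One-way ANOVA F ratio and p-value per protein, with retention flags.

    Degenerate rows: zero variance both between and within groups gives
    F = 0, p = 1 (no signal); zero within-group variance with non-zero
    between-group variance gives F = inf, p = 0 (perfect separation,
    retained).
    """
    if matrix.column_kind != "run":
        raise ValueError("f_screen expects a run-level matrix")
    runs = matrix.columns
    labels = _group_labels(design, grouping, runs)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    X = matrix.data.to_numpy(dtype=float)  # proteins x runs
    n_total = X.shape[1]
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for g in groups:
        cols = labels == g
        n_g = int(cols.sum())
        m_g = X[:, cols].mean(axis=1)
        ss_between += n_g * (m_g - grand) ** 2
        ss_within += ((X[:, cols] - m_g[:, None]) ** 2).sum(axis=1)
    df1 = len(groups) - 1
    df2 = n_total - len(groups)
    if df2 <= 0:
        raise ValueError("need more runs than groups")
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    tol = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_within > tol, ms_between / np.where(ms_within > tol, ms_within, 1.0), np.inf)
    f = np.where((ss_within <= tol) & (ss_between <= tol), 0.0, f)
    p = np.where(np.isinf(f), 0.0, st.f.sf(np.where(np.isinf(f), 1.0, f), df1, df2))
    p = np.where(f == 0.0, 1.0, p)
    retained = (f >= f_min) & (p <= p_max)
    return [
        ScreenResult(prot, float(f[i]), float(p[i]), bool(retained[i]))
        for i, prot in enumerate(matrix.proteins)
    ]


def retained_proteins(results: list[ScreenResult]) -> list[str]:
    return [r.protein for r in results if r.retained]


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class Dendrogram:
    """Ward/Euclidean agglomeration of column profiles.

    ``linkage`` is a scipy linkage matrix over ``labels`` (columns are
    sorted lexicographically before clustering so the result is invariant
    to input column order).
    """

    linkage: np.ndarray
    labels: list[str]

    def top_split(self) -> tuple[set[str], set[str]]:
        """Leaf labels of the two children of the root merge."""
        n = len(self.labels)
        members: list[set[int]] = [{i} for i in range(n)]
        for row in self.linkage:
            members.append(members[int(row[0])] | members[int(row[1])])
        left, right = int(self.linkage[-1][0]), int(self.linkage[-1][1])
        lab = lambda s: {self.labels[i] for i in s}
        return lab(members[left]), lab(members[right])

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            row = self.linkage[i - n]
            a, b = int(row[0]), int(row[1])
            h = row[2]
            return (
                f"({node(a)}:{h - heights[a]:.6g},{node(b)}:{h - heights[b]:.6g})"
            )

        for idx, row in enumerate(self.linkage):
            heights[n + idx] = row[2]
        return node(n + len(self.linkage) - 1) + ";"


def cluster(matrix: CountMatrix, standardize: bool = True) -> Dendrogram:
    """Ward-linkage hierarchical clustering of column profiles.

    With ``standardize=True`` (default, as in JMP's clustering platform)
    each protein row is z-scored across columns first, so every retained
    protein contributes equally to the Euclidean distances; otherwise raw
    profiles are used and high-abundance proteins dominate.
    """
    if matrix.data.shape[1] < 2:
        raise ValueError("need at least 2 columns to cluster")
    if np.isnan(matrix.data.to_numpy()).any():
        raise ValueError("NaN in matrix")
    cols = sorted(matrix.columns)
    X = matrix.data[cols].to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    Z = sch.linkage(X.T, method="ward", metric="euclidean")
    return Dendrogram(Z, cols)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # columns (samples) x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: CountMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of column profiles (conditions as samples, proteins as features).

    Protein rows are centred across columns; components are ordered by
    decreasing explained variance.
    """
    X = matrix.data.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("need at least 2 columns for PCA")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        pd.DataFrame(model.components_.T, index=matrix.proteins, columns=comp_names),
        model.explained_variance_ratio_,
    )


def combine_selections(
    screen_set: set[str] | list[str], dep_set: set[str] | list[str]
) -> dict[str, set[str]]:
    """Union of the F-screen and DEP selections with provenance flags.

    Returns protein -> subset of {"screen", "dep"}.
    """
    out: dict[str, set[str]] = {}
    for p in screen_set:
        out.setdefault(p, set()).add("screen")
    for p in dep_set:
        out.setdefault(p, set()).add("dep")
    return out


def discriminant_projection(
    matrix: CountMatrix, design: ConditionDesign, grouping: str | list[str] = "condition"
) -> pd.DataFrame:
    """Optional diagnostic: project runs on linear discriminant axes."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = _group_labels(design, grouping, matrix.columns)
    X = matrix.data.to_numpy(dtype=float).T
    lda = LinearDiscriminantAnalysis()
    scores = lda.fit_transform(X, labels)
    cols = [f"LD{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.columns, columns=cols)
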