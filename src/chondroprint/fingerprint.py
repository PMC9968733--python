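"""Multivariate fingerprinting: clustered image maps and PLS-DA.

The fingerprinting stage asks which combination of shape descriptors and
gene-expression levels discriminates control from inflammatory (IL-1β-like)
samples.

* ``scale_center`` z-scores each feature column (the heatmap color key is
  then in SD units away from the feature mean).
* ``cim`` builds a clustered image map: hierarchical agglomerative
  clustering of rows (samples) and columns (features) on Euclidean
  distances of the z-scored matrix.  Complete linkage is the default,
  configurable to average or Ward.
* ``plsda_fit`` is a from-scratch NIPALS partial-least-squares fit against
  the dummy-coded class vector (control 0, treated 1; both X and the class
  column are centered).  For a univariate response the weight of each
  component has the closed form ``w ∝ Xᵀ(y − ȳ)`` on the deflated data;
  the iterative loop is retained for the general (multi-column Y) case.
  Successive score vectors are mutually orthogonal.
* ``rank_discriminative_features`` reads per-feature importance from the
  component-1 X-loadings: the magnitude ranks importance, the sign assigns
  the feature to the class it marks (score signs are normalized so that a
  positive loading points at class 1).

No cross-validated component selection, VIP scores or sparse variants: the
loading bars themselves are the readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ScaleParams", "CIMResult", "PLSDAModel",
    "scale_center", "cim", "plsda_fit", "rank_discriminative_features",
]


# --------------------------------------------------------------------------
# Scaling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleParams:
    """Column means/SDs retained for inverse mapping."""

    mean: pd.Series
    sd: pd.Series

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        return z * self.sd + self.mean


def scale_center(
    matrix: pd.DataFrame, ddof: int = 1
) -> tuple[pd.DataFrame, ScaleParams]:
    """Column-wise z-scores (mean 0, SD 1).  Constant columns are dropped
    with a warning; an all-constant matrix is an error."""
    num = matrix.select_dtypes(include=[np.number])
    sd = num.std(ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant")
    if not keep.all():
        warnings.warn(
            f"dropping constant columns: {list(sd.index[~keep])}")
    num = num.loc[:, keep]
    mean = num.mean()
    sd = sd[keep]
    return (num - mean) / sd, ScaleParams(mean=mean, sd=sd)


# --------------------------------------------------------------------------
# Clustered image map
# --------------------------------------------------------------------------

@dataclass
class CIMResult:
    """Z-scored matrix with dendrogram orders (color scale is in SD units)."""

    z: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    row_classes: pd.Series | None
    cluster_vs_class: pd.DataFrame | None

    def reordered(self) -> pd.DataFrame:
        return self.z.iloc[self.row_order, self.col_order]

    def row_clusters(self, k: int) -> np.ndarray:
        return fcluster(self.row_linkage, k, criterion="maxclust")


def cim(
    matrix: pd.DataFrame,
    row_classes: pd.Series | None = None,
    method: str = "complete",
) -> CIMResult:
    """Clustered image map of a sample × feature matrix.

    Rows and columns are clustered hierarchically on Euclidean distances of
    the z-scored data.  If per-row class labels are given, a 2-cluster
    cut of the row tree is cross-tabulated against them.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows")
    z, _ = scale_center(matrix)
    row_link = linkage(pdist(z.values), method=method)
    col_link = linkage(pdist(z.values.T), method=method)
    result = CIMResult(
        z=z,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=list(leaves_list(row_link)),
        col_order=list(leaves_list(col_link)),
        row_classes=row_classes,
        cluster_vs_class=None,
    )
    if row_classes is not None:
        clusters = result.row_clusters(2)
        result.cluster_vs_class = pd.crosstab(
            pd.Series(clusters, index=z.index, name="cluster"),
            pd.Series(np.asarray(row_classes), index=z.index, name="class"))
    return result


# --------------------------------------------------------------------------
# PLS-DA (NIPALS)
# --------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    """Fitted PLS-DA decomposition against a 0/1 class vector.

    Per component: unit-norm weights ``w``, scores ``t = X w`` (on deflated
    data), X-loadings ``p = Xᵀt / tᵀt`` and y-loadings ``q``.  Score signs
    are normalized so each component's score correlates positively with the
    class vector, hence a positive component-1 loading marks class 1.
    """

    feature_names: list[str]
    ncomp: int
    weights: np.ndarray      # (p, ncomp)
    x_loadings: np.ndarray   # (p, ncomp)
    y_loadings: np.ndarray   # (ncomp,)
    scores: np.ndarray       # (n, ncomp)
    y_mean: float
    x_variance_explained: np.ndarray  # fraction of total X SS per component

    @property
    def importance(self) -> pd.Series:
        """Per-feature importance: signed component-1 X-loading."""
        return pd.Series(self.x_loadings[:, 0], index=self.feature_names,
                         name="loading1")


def plsda_fit(
    X: pd.DataFrame | np.ndarray,
    y,
    ncomp: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAModel:
    """Fit PLS-DA by NIPALS on (preferably z-scored) features.

    ``y`` is the 0/1 class vector; both X and y are centered internally.
    Initialization is deterministic (the centered class column), so the fit
    involves no randomness.
    """
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{i}" for i in range(np.asarray(X).shape[1])])
    Xw = np.asarray(X, dtype=float).copy()
    yv = np.asarray(y, dtype=float).ravel()
    if Xw.ndim != 2 or Xw.shape[0] != len(yv):
        raise ValueError("X rows must match y length")
    classes = np.unique(yv)
    if len(classes) < 2:
        raise ValueError("y is degenerate (single class)")
    n, p = Xw.shape
    rank_cap = min(n - 1, p)
    if ncomp > rank_cap:
        raise ValueError(f"ncomp={ncomp} exceeds min(n-1, p)={rank_cap}")

    Xw = Xw - Xw.mean(axis=0)
    y_mean = float(yv.mean())
    yc = (yv - y_mean).reshape(-1, 1)

    total_ss = float((Xw**2).sum())
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    xve = np.zeros(ncomp)

    for a in range(ncomp):
        u = yc[:, 0].copy()
        if np.allclose(u, 0):
            raise ValueError("class vector fully deflated; reduce ncomp")
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xw.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                raise ValueError("zero weight vector; X fully deflated")
            w_new /= nrm
            t = Xw @ w_new
            q = float(yc[:, 0] @ t / (t @ t))
            u_new = yc[:, 0] * q  # univariate Y: u ∝ y, converges in 1 step
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
            u = u_new
        t = Xw @ w
        # Sign convention: scores correlate positively with the class.
        if (t @ yc[:, 0]) < 0:
            w, t = -w, -t
        pt = Xw.T @ t / (t @ t)
        q = float(yc[:, 0] @ t / (t @ t))
        Xw = Xw - np.outer(t, pt)
        yc = yc - (t * q).reshape(-1, 1)
        W[:, a], P[:, a], Q[a], T[:, a] = w, pt, q, t
        xve[a] = float((t @ t) * (pt @ pt)) / total_ss if total_ss else 0.0

    return PLSDAModel(feature_names=names, ncomp=ncomp, weights=W,
                      x_loadings=P, y_loadings=Q, scores=T,
                      y_mean=y_mean, x_variance_explained=xve)


def rank_discriminative_features(model: PLSDAModel) -> pd.DataFrame:
    """Rank features by |component-1 loading|; assign each to the class its
    loading sign points to (positive → class 1, negative → class 0).

    This is the tabular analog of the loading-vector bar plots whose bar
    lengths express how important a feature is for discriminating control
    from treated phenotypes.
    """
    load = model.importance
    out = pd.DataFrame({
        "feature": load.index,
        "loading": load.values,
        "importance": np.abs(load.values),
        "marks_class": (load.values > 0).astype(int),
    })
    out = out.sort_values("importance", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
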