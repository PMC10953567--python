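"""Correlation structure, hierarchical clustering, k-cut profiles, and PCA.

Defaults follow common phosphoproteome-heatmap practice: 1 − Pearson
correlation distance with average linkage, row z-scoring before feature
clustering, and a 2-df chi-square confidence ellipse per sample group in PC
space. Principal-component signs are fixed by making each component's
largest-magnitude loading positive, so outputs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import ConfigurationError, ValidationError
from .io import sample_groups
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


def _as_frame(m) -> pd.DataFrame:
    return m.data if isinstance(m, NormalizedMatrix) else m


@dataclass
class CorrelationResult:
    r: pd.DataFrame  # Pearson r over pairwise-complete values
    n: pd.DataFrame  # pairwise-complete observation counts


def correlation_matrix(m: NormalizedMatrix | pd.DataFrame) -> CorrelationResult:
    """Column-by-column Pearson r over pairwise-complete observations."""
    X = _as_frame(m)
    r = X.corr(method="pearson", min_periods=2)
    np.fill_diagonal(r.values, 1.0)
    obs = X.notna().astype(int)
    n = obs.T @ obs
    return CorrelationResult(r=r, n=pd.DataFrame(n, index=X.columns, columns=X.columns))


@dataclass
class Dendrogram:
    Z: np.ndarray            # scipy linkage matrix
    labels: list[str]
    linkage: str
    distance: str

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.Z)]


def _condensed_distance(X: pd.DataFrame, distance: str) -> np.ndarray:
    if distance == "correlation":
        r = X.T.corr(method="pearson", min_periods=2)
        d = 1.0 - r.to_numpy()
        np.fill_diagonal(d, 0.0)
        if np.isnan(d).any():
            raise ValidationError(
                "correlation distance undefined for some row pairs "
                "(fewer than 2 shared observations)"
            )
        iu = np.triu_indices(len(d), k=1)
        return np.maximum(d[iu], 0.0)
    if distance == "euclidean":
        arr = X.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("euclidean distance requires complete rows")
        from scipy.spatial.distance import pdist

        return pdist(arr)
    raise ConfigurationError(f"unknown distance {distance!r}")


def hcluster(
    m: NormalizedMatrix | pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the rows of ``m``."""
    X = _as_frame(m)
    if len(X) < 2:
        raise ValidationError("hierarchical clustering needs at least 2 items")
    if linkage not in ("average", "complete", "ward"):
        raise ConfigurationError(f"unknown linkage {linkage!r}")
    y = _condensed_distance(X, distance)
    Z = hierarchy.linkage(y, method=linkage)
    return Dendrogram(Z=Z, labels=list(X.index), linkage=linkage, distance=distance)


def to_newick(d: Dendrogram) -> str:
    """Nested-parenthesis text rendering of the dendrogram."""
    tree = hierarchy.to_tree(d.Z)

    def rec(node) -> str:
        if node.is_leaf():
            return d.labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


@dataclass
class ClusterProfiles:
    labels: pd.Series                 # feature -> cluster id 1..k
    profiles: pd.DataFrame | None = None  # (cluster, group) mean of z-scored rows


def cut_k(
    d: Dendrogram,
    k: int,
    m: NormalizedMatrix | pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
) -> ClusterProfiles:
    """Cut the dendrogram into exactly k clusters; optionally add group profiles."""
    flat = hierarchy.fcluster(d.Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=d.labels, name="cluster")
    profiles = None
    if m is not None and sheet is not None:
        X = _as_frame(m).loc[d.labels]
        mu = X.mean(axis=1, skipna=True)
        sd = X.std(axis=1, ddof=0, skipna=True).replace(0.0, np.nan)
        z = X.sub(mu, axis=0).div(sd, axis=0)
        groups = sample_groups(sheet)
        recs = {}
        for g in groups.unique():
            cols = [c for c in X.columns if groups.get(c) == g]
            recs[g] = z[cols].mean(axis=1, skipna=True)
        per_group = pd.DataFrame(recs)
        profiles = per_group.groupby(labels).mean()
    return ClusterProfiles(labels=labels, profiles=profiles)


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples × components
    explained: np.ndarray           # variance fractions, sums to 1
    ellipses: dict[str, dict] = field(default_factory=dict)
    loadings: pd.DataFrame | None = None


def pca_with_ellipses(
    m: NormalizedMatrix | pd.DataFrame,
    sheet: pd.DataFrame,
    level: float = 0.95,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of the sample × feature matrix with per-group chi-square ellipses.

    Features are standardized (mean 0, unit variance) before decomposition;
    features with any missing value across the included samples are dropped.
    Each group with >= 3 samples gets a 2-df chi-square "error ellipse" at the
    requested confidence level, computed from its score covariance in PC1/PC2.
    """
    if not 0.0 < level < 1.0:
        raise ConfigurationError("confidence level must lie in (0, 1)")
    X = _as_frame(m).T  # samples × features
    complete = X.columns[X.notna().all(axis=0)]
    if len(complete) < len(X.columns):
        logger.info("pca: dropping %d incomplete features", len(X.columns) - len(complete))
    X = X[complete]
    arr = X.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    keep = sd > 0
    arr = arr[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(arr, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * S
    explained = S**2 / np.sum(S**2)
    k = n_components or scores.shape[1]
    score_df = pd.DataFrame(
        scores[:, :k], index=X.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    load_df = pd.DataFrame(
        Vt[:k].T, index=X.columns[keep], columns=score_df.columns
    )
    groups = sample_groups(sheet)
    ellipses: dict[str, dict] = {}
    q = stats.chi2.ppf(level, df=2)
    for g in sorted(groups.unique()):
        rows = [s for s in score_df.index if groups.get(s) == g]
        if len(rows) < 3:
            logger.warning("pca: group %s has < 3 samples; ellipse omitted", g)
            continue
        pts = score_df.loc[rows, ["PC1", "PC2"]].to_numpy()
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        ellipses[g] = {
            "center": pts.mean(axis=0).tolist(),
            "semi_axes": np.sqrt(np.maximum(evals, 0.0) * q).tolist(),
            "angle_deg": float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0]))),
            "level": level,
            "n": len(rows),
        }
    return PcaResult(scores=score_df, explained=explained, ellipses=ellipses,
                     loadings=load_df)
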