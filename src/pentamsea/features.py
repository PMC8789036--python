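"""Pentamers in motif-feature space: binary membership matrix, PCA, cluster
separation.

Each pentamer is encoded as a binary vector over the size-filtered motif
sets (1 where the pentamer belongs to the set).  Column-centered PCA of
this matrix projects the library into the six-layer feature space; the
silhouette of the sign(ΔPSI) groups in the leading components quantifies
how well the feature space separates stimulatory from inhibitory pentamers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .library import enumerate_library
from .sets import LAYERS, MotifSetCollection

_LAYER_RANK = {layer: i for i, layer in enumerate(LAYERS)}


def build_features(library: list[str] | None, sets: MotifSetCollection
                   ) -> pd.DataFrame:
    """Binary pentamer × motif-set membership matrix.

    Columns are ordered by (layer, set_id) for determinism; the per-column
    layer tags are kept in ``df.attrs["layers"]``.
    """
    if len(sets) == 0:
        raise ValueError("cannot build features from an empty collection")
    library = library if library is not None else enumerate_library()
    ordered = sorted(sets, key=lambda s: (_LAYER_RANK[s.layer], s.set_id))
    pos = {p: i for i, p in enumerate(library)}
    mat = np.zeros((len(library), len(ordered)), dtype=np.int8)
    for j, s in enumerate(ordered):
        mat[[pos[m] for m in s.members], j] = 1
    df = pd.DataFrame(mat, index=pd.Index(library, name="pentamer"),
                      columns=[s.set_id for s in ordered])
    df.attrs["layers"] = {s.set_id: s.layer for s in ordered}
    return df


class MotifFeaturePCA(BaseEstimator, TransformerMixin):
    """Column-centered PCA of the membership matrix (SVD, unscaled).

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores reproducible across runs.

    Attributes
    ----------
    components_ : ndarray (k, M)
    explained_variance_ratio_ : ndarray (k,)
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None) -> "MotifFeaturePCA":
        X = np.asarray(X, dtype=float)
        if self.n_components > min(X.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(matrix dims)="
                f"{min(X.shape)}")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(X)
        flip = np.sign(self._pca.components_[
            np.arange(self._pca.components_.shape[0]),
            np.argmax(np.abs(self._pca.components_), axis=1)])
        flip[flip == 0] = 1.0
        self._flip = flip
        self.components_ = self._pca.components_ * flip[:, None]
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_.copy()
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self._pca.transform(np.asarray(X, dtype=float)) * self._flip


def run_pca(features: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Project pentamers onto the first k principal components.

    Returns a DataFrame of scores (columns PC1..PCk) with the variance
    fractions stored in ``result.attrs["explained_variance_ratio"]``.
    """
    est = MotifFeaturePCA(n_components=k).fit(features)
    scores = est.transform(features)
    out = pd.DataFrame(scores, index=features.index,
                       columns=[f"PC{i + 1}" for i in range(k)])
    out.attrs["explained_variance_ratio"] = est.explained_variance_ratio_.tolist()
    return out


def separation_score(scores: pd.DataFrame, delta_psi: pd.Series) -> float:
    """Mean silhouette of the stimulatory (ΔPSI > 0) vs inhibitory
    (ΔPSI < 0) pentamer groups in PCA-score space; zeros are excluded."""
    labels = np.sign(delta_psi.reindex(scores.index))
    keep = labels != 0
    labels = labels[keep]
    if (labels > 0).sum() < 2 or (labels < 0).sum() < 2:
        raise ValueError("each ΔPSI sign group needs at least 2 pentamers")
    return float(silhouette_score(scores.to_numpy(dtype=float)[keep.to_numpy()],
                                  labels.to_numpy()))


def plot_pca_3d(scores: pd.DataFrame, delta_psi: pd.Series, path) -> None:
    """3-D scatter of the first three components, colored by ΔPSI sign."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = delta_psi.reindex(scores.index)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], scores.iloc[:, 2],
               c=np.where(d > 0, "crimson", np.where(d < 0, "royalblue", "grey")),
               s=8, alpha=0.6)
    evr = scores.attrs.get("explained_variance_ratio")
    for i, axis_set in enumerate((ax.set_xlabel, ax.set_ylabel, ax.set_zlabel)):
        label = scores.columns[i]
        if evr:
            label += f" ({100 * evr[i]:.1f}%)"
        axis_set(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
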