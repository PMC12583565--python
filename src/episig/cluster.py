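"""Unsupervised structure assessment: hierarchical clustering and MDS.

Both operate on the beta values of the selected episignature probes (the
heatmap convention of methylation fractions).  Samples are sorted by id
before any distance computation so results are invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .dmp import EpisignatureProbeSet
from .types import BetaMatrix, ValidationError

__all__ = ["Dendrogram", "Embedding2D", "hierarchical_cluster", "cut_two",
           "mds_embed"]


@dataclass
class Dendrogram:
    """Agglomerative merge history over named leaves.

    ``merges`` is the scipy linkage matrix (n-1 x 4); row i merges the
    clusters indexed by columns 0 and 1 (indices >= n refer to earlier
    merge rows) at height column 2, forming cluster n+i of size column 3.
    """

    leaf_ids: list[str]
    merges: np.ndarray
    linkage_method: str
    metric: str

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ValidationError(
                f"merge matrix shape {self.merges.shape} inconsistent with "
                f"{n} leaves"
            )

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = leaves_list(self.merges) if len(self.merges) else [0]
        return [self.leaf_ids[i] for i in order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return {leaf: int(lab) for leaf, lab in zip(self.leaf_ids, labels)}

    def to_dict(self) -> dict:
        return {
            "leaf_ids": list(self.leaf_ids),
            "merges": self.merges.tolist(),
            "linkage_method": self.linkage_method,
            "metric": self.metric,
        }


def hierarchical_cluster(
    beta: BetaMatrix,
    probe_set: EpisignatureProbeSet | Sequence[str],
    metric: str = "euclidean",
    linkage_method: str = "ward",
    sample_ids: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of samples over the signature probes.

    Samples are ordered by id before linkage, giving a deterministic
    dendrogram regardless of input order.
    """
    probes = (probe_set.probe_ids if isinstance(probe_set, EpisignatureProbeSet)
              else list(probe_set))
    ids = sorted(sample_ids) if sample_ids is not None else sorted(beta.sample_ids)
    if len(ids) < 2:
        raise ValidationError(f"clustering needs >=2 samples, got {len(ids)}")
    x = beta.subset(probes=probes, samples=ids).values.T
    merges = linkage(x, method=linkage_method, metric=metric)
    return Dendrogram(leaf_ids=ids, merges=merges,
                      linkage_method=linkage_method, metric=metric)


def cut_two(dendrogram: Dendrogram) -> dict[str, int]:
    """Convenience 2-cluster cut (case-branch membership checks)."""
    return dendrogram.cut(2)


@dataclass
class Embedding2D:
    """Low-dimensional metric embedding of samples (centered coordinates)."""

    coordinates: pd.DataFrame  # index sample_id, columns dim1..dimK

    def __post_init__(self) -> None:
        means = self.coordinates.to_numpy().mean(axis=0)
        if np.any(np.abs(means) > 1e-6 * max(1.0, np.abs(self.coordinates.to_numpy()).max())):
            raise ValidationError("embedding coordinates are not centered")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)

    def xy(self, sample_id: str) -> np.ndarray:
        return self.coordinates.loc[sample_id].to_numpy()


def mds_embed(
    beta: BetaMatrix,
    probe_set: EpisignatureProbeSet | Sequence[str],
    dims: int = 2,
    sample_ids: Sequence[str] | None = None,
) -> Embedding2D:
    """Classical (Torgerson) metric MDS on Euclidean distances.

    The squared-distance matrix is double-centered, and the top ``dims``
    eigenvectors scaled by root-eigenvalues give the coordinates.  For
    intrinsically low-dimensional Euclidean data this reproduces the
    input distances exactly.  Axis signs are fixed so the first nonzero
    loading of each axis is positive.
    """
    probes = (probe_set.probe_ids if isinstance(probe_set, EpisignatureProbeSet)
              else list(probe_set))
    ids = sorted(sample_ids) if sample_ids is not None else sorted(beta.sample_ids)
    n = len(ids)
    if n < dims + 1:
        raise ValidationError(
            f"MDS with dims={dims} needs more than {dims} samples, got {n}"
        )
    x = beta.subset(probes=probes, samples=ids).values.T
    d2 = squareform(pdist(x, metric="euclidean")) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:dims]
    coords = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0.0, None))
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nonzero = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nonzero) and col[nonzero[0]] < 0:
            coords[:, k] = -col
    coords = coords - coords.mean(axis=0)
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"dim{k+1}" for k in range(dims)])
    return Embedding2D(frame)
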