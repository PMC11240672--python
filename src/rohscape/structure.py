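"""Genomic similarity between individuals: IBS distance and classical MDS.

Identity-by-state similarity between two genotypes is the mean, over markers
non-missing in both, of shared alleles / 2 (dosage codes: shared alleles =
``2 - |g1 - g2|``).  Distance is 1 - similarity.  Classical multidimensional
scaling (principal coordinates) embeds the distance matrix via the
eigendecomposition of the double-centered squared distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    """Symmetric 1 - IBS distance with zero diagonal.

    Entries lie in [0, 1]; a pair with no jointly non-missing marker is NaN.
    """

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        self.values = v


def ibs_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise 1 - IBS distance between all samples.

    Computed with indicator-matrix products so missing calls are excluded
    pairwise: shared-allele sum = 2 * (#agreeing markers) + 1 * (#markers
    differing by one dosage), i.e. ``agree + joint - opposite``.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    g = ds.genotypes
    a = [(g == v).astype(np.float64) for v in (0, 1, 2)]
    called = (g != MISSING).astype(np.float64)
    joint = called @ called.T
    agree = sum(x @ x.T for x in a)
    opposite = a[0] @ a[2].T
    opposite = opposite + opposite.T
    shared = agree + joint - opposite
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(joint > 0, shared / (2 * np.maximum(joint, 1)), np.nan)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce exact symmetry against fp noise
    return DistanceMatrix(ds.sample_ids.tolist(), dist)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Parameters
    ----------
    dist
        Distance matrix; must be NaN-free.
    k
        Number of components, ``1 <= k <= n - 1``.

    Returns
    -------
    coords : DataFrame
        ``sample_id, C1..Ck``; signs fixed so the first sample has
        nonnegative coordinates.
    explained : ndarray
        Each returned component's share of the sum of positive eigenvalues.

    Raises
    ------
    ValueError
        If the negative-eigenvalue mass exceeds the positive mass (the
        matrix is not even approximately Euclidean-embeddable).
    """
    d = dist.values
    n = d.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError("k must lie in [1, n-1]")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing entries")
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval[eigval > 1e-12]
    neg_mass = float(-eigval[eigval < 0].sum())
    pos_mass = float(pos.sum())
    if neg_mass > pos_mass:
        raise ValueError("negative eigenvalue mass exceeds positive; not MDS-able")
    lam = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)
    # deterministic sign: first sample nonnegative on every component
    for c in range(k):
        ref = coords[0, c]
        if ref < 0 or (ref == 0 and (coords[:, c] < 0).any() and coords[:, c].sum() < 0):
            coords[:, c] = -coords[:, c]
    explained = lam / pos_mass if pos_mass > 0 else np.zeros(k)
    df = pd.DataFrame(coords, columns=[f"C{i+1}" for i in range(k)])
    df.insert(0, "sample_id", dist.sample_ids)
    return df, explained


class IBSMDS(BaseEstimator):
    """IBS distance + classical MDS, sklearn-style.

    Attributes
    ----------
    distance_ : DistanceMatrix
    embedding_ : ndarray of shape (n_samples, n_components)
    explained_variance_ratio_ : ndarray
    coordinates_ : pandas.DataFrame
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: GenotypeDataset, y=None) -> "IBSMDS":
        self.distance_ = ibs_distance(X)
        self.coordinates_, self.explained_variance_ratio_ = classical_mds(
            self.distance_, self.n_components
        )
        self.embedding_ = self.coordinates_.drop(columns="sample_id").to_numpy()
        return self

    def fit_transform(self, X: GenotypeDataset, y=None) -> np.ndarray:
        return self.fit(X).embedding_
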