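"""Pairwise epigenetic distances, principal coordinates and Mantel tests.

Samples are compared on their concatenated (M, H) call vectors.  The default
metric is ``squared_euclidean`` — on binary data the count of differing calls,
the convention binary-marker AMOVA operates on.  Bands with a missing call in
either member of a pair are dropped for that pair (pairwise deletion) and the
mismatch count is rescaled to the full band count, so distances from sparse
and complete pairs stay on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .band_data import BandMatrix

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "MantelResult",
    "pairwise_distance",
    "pcoa",
    "mantel",
]

METRICS = ("squared_euclidean", "euclidean", "jaccard", "simple_matching")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample ids and a metric tag.

    The tag matters downstream: ``squared_euclidean`` entries are already
    squared distances and are consumed as such by PCoA and AMOVA.
    """

    sample_ids: list[str]
    data: np.ndarray
    metric: str = "squared_euclidean"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def squared(self) -> np.ndarray:
        """Entries as squared distances, whatever the stored convention."""
        return self.data if self.metric == "squared_euclidean" else self.data**2

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]

    def reorder(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.data[np.ix_(idx, idx)], self.metric)


def pairwise_distance(matrix: BandMatrix, metric: str = "squared_euclidean") -> DistanceMatrix:
    """All-pairs dissimilarity on concatenated M and H calls."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.band_table().to_numpy()  # NaN marks missing
    ok = ~np.isnan(x)
    x0 = np.nan_to_num(x)
    n, b = x.shape
    d = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        shared = both.sum(axis=1)
        if np.any(shared == 0):
            j = int(np.flatnonzero(shared == 0)[0]) + i + 1
            raise ValueError(
                f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
                "share no scored band"
            )
        xi = x0[i]
        xj = x0[i + 1:]
        diff = np.abs(xi - xj) * both
        mism = diff.sum(axis=1)
        if metric in ("squared_euclidean", "euclidean", "simple_matching"):
            scaled = mism * (b / shared)  # rescale to full band count
            if metric == "squared_euclidean":
                row = scaled
            elif metric == "euclidean":
                row = np.sqrt(scaled)
            else:
                row = mism / shared
        else:  # jaccard: mismatches over union of presences
            union = (((xi + xj) > 0) & both).sum(axis=1)
            row = np.where(union > 0, mism / np.maximum(union, 1), 0.0)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return DistanceMatrix(list(matrix.sample_ids), d, metric)


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` is samples x retained axes (positive eigenvalues only),
    centered so every axis sums to zero; ``pct_explained`` is relative to the
    sum of positive eigenvalues; any dropped negative eigenvalue magnitude is
    reported in ``negative_eigenvalue_magnitude``.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_explained: np.ndarray
    negative_eigenvalue_magnitude: float = 0.0
    notices: list[str] = field(default_factory=list)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical (metric) MDS by Gower double-centering.

    The centered matrix is -0.5 * D2 double-centered, where D2 is the matrix
    of squared distances (taken directly from a ``squared_euclidean`` input,
    squared otherwise).  Coordinates are eigenvectors scaled by the square
    root of their positive eigenvalues; negative-eigenvalue axes are dropped
    and their total magnitude reported.  No Cailliez/Lingoes correction is
    applied by default.
    """
    d2 = d.squared()
    n = d.n
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * (j @ d2 @ j)
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals).max()) if n else 0.0
    pos = evals > tol
    neg_mag = float(-evals[evals < -tol].sum())
    notices = []
    rank = int(pos.sum())
    if n_axes > rank:
        notices.append(f"requested {n_axes} axes but only {rank} positive; returning {rank}")
        n_axes = rank
    lam = evals[pos][:n_axes]
    coords = evecs[:, pos][:, :n_axes] * np.sqrt(lam)
    pct = 100.0 * lam / evals[pos].sum() if rank else lam
    if neg_mag > 0:
        notices.append(f"dropped negative eigenvalue mass {neg_mag:.6g}")
    return PcoaResult(list(d.sample_ids), coords, lam, pct, neg_mag, notices)


@dataclass(frozen=True)
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same samples.

    r is the Pearson correlation of the upper-triangle entries; significance
    comes from jointly permuting rows and columns of the second matrix, with
    a one-tailed (greater) p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1).
    """
    if set(d1.sample_ids) != set(d2.sample_ids):
        raise ValueError("Mantel requires identical sample sets")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    d2 = d2.reorder(d1.sample_ids)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x = d1.data[iu]
    if np.std(x) == 0 or np.std(d2.data[iu]) == 0:
        raise ValueError("zero-variance distance matrix; Mantel r undefined")
    xs = (x - x.mean()) / x.std()

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        return float(np.dot(xs, (y - y.mean()) / y.std()) / len(x))

    r_obs = corr(d2.data)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(d2.data[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return MantelResult(r_obs, r_obs**2, p, n_permutations, seed)
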