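"""Alpha/beta diversity, principal coordinates, and PERMANOVA.

Shannon entropy and Bray-Curtis dissimilarity are the alpha/beta measures;
ordination is classical scaling (PCoA) of the Bray-Curtis matrix; the group
test is Anderson's permutational MANOVA (pseudo-F on the partition of squared
distances, p by free permutation of group labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .abundance import AbundanceTable, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "shannon",
    "shannon_per_sample",
    "bray_curtis",
    "pcoa",
    "permanova",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x axes
    explained: np.ndarray  # fraction of positive eigenvalue mass per axis
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None


def shannon(counts, log_base: str | float = "e") -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with p_i > 0."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if log_base in ("e", np.e):
        return h
    if log_base == 2 or log_base == "2":
        return h / np.log(2)
    return h / np.log(float(log_base))


def shannon_per_sample(table: AbundanceTable, log_base: str | float = "e") -> dict[str, float]:
    return {s: shannon(row, log_base) for s, row in zip(table.sample_ids, table.counts)}


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis: d = 1 - 2*sum(min(x,y)) / (sum x + sum y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.sample_sums() == 0).any():
        raise ValueError("sample with zero total reads")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis).

    Double-centres -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues. Negative eigenvalues are
    reported but excluded from the explained-variance denominator; axes are
    sign-oriented so each column's largest-magnitude loading is positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    n = dm.n
    a = -0.5 * dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    rank = int(pos.sum())
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but positive-eigenvalue rank is {rank}; truncating",
            stacklevel=2,
        )
        n_axes = max(rank, 1)
    k = min(n_axes, rank)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    # deterministic sign: orient each axis so its largest |coordinate| is positive
    for c in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, c]))
        if coords[pivot, c] < 0:
            coords[:, c] = -coords[:, c]
    pos_mass = evals[pos].sum()
    explained = evals[:k] / pos_mass if pos_mass > 0 else np.zeros(k)
    return OrdinationResult(list(dm.ids), coords, explained, evals)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and group labels."""
    n = d2.shape[0]
    groups, inverse = np.unique(labels, return_inverse=True)
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(inverse == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA (Adonis-style) on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), free
    permutation of group labels, deterministic given `seed`. With
    ``n_permutations="exhaustive"`` every distinct label assignment is
    enumerated and p = #{F >= F_obs} / #assignments (the observed labelling
    is one of them), which is exact on small designs.
    """
    labels = meta.groups_for(dm.ids)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    d2 = dm.d**2
    f_obs = _pseudo_f(d2, labels)
    if n_permutations == "exhaustive":
        from itertools import permutations as iperm

        seen = set()
        hits = 0
        for perm in iperm(labels):
            if perm in seen:
                continue
            seen.add(perm)
            if _pseudo_f(d2, np.array(perm)) >= f_obs - 1e-12:
                hits += 1
        p = hits / len(seen)
        return PermanovaResult(float(f_obs), float(p), len(seen), seed)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)
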