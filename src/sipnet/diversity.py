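"""Alpha diversity, Bray–Curtis beta diversity, PCoA, and a permutation
test of group separation.

Community dissimilarity uses the Bray–Curtis index
``Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ)``, embedded by classical scaling (PCoA with Gower
centering). Group separation on a distance matrix is tested with a
PERMANOVA-style pseudo-F statistic under label permutation; the p-value
uses the add-one estimator ``(1 + #{F* ≥ F}) / (1 + n_perm)`` so that
p = 0 is unattainable. Every stochastic routine takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateInputError, EmptyInputError


# ---------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------

def observed_richness(sample_counts: Sequence[float]) -> int:
    """Number of OTUs with a nonzero count."""
    arr = np.asarray(sample_counts)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return int((arr > 0).sum())


def inverse_simpson(sample_counts: Sequence[float]) -> float:
    """Inverse Simpson index 1 / Σ pᵢ².

    Equals the number of OTUs for a perfectly even community and 1 for a
    single-OTU community; bounded above by observed richness.
    """
    arr = np.asarray(sample_counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise EmptyInputError("inverse Simpson undefined for an empty sample")
    p = arr / total
    return float(1.0 / np.sum(p**2))


# ---------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------

def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ), in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = (u + v).sum()
    if denom == 0:
        raise DegenerateInputError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


def bray_curtis_matrix(profiles: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """All-pairs Bray–Curtis over the rows of ``profiles``.

    Returns (row labels, symmetric matrix with zero diagonal).
    """
    values = profiles.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        raise DegenerateInputError("all-zero row; Bray-Curtis undefined")
    dm = squareform(pdist(values, metric="braycurtis"))
    return list(profiles.index), dm


# ---------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------

@dataclass
class Ordination:
    """Result of classical scaling of a distance matrix.

    ``eigenvalues`` holds the full descending spectrum of the
    Gower-centered matrix (negatives included, for diagnostics);
    ``coordinates`` and ``proportion_explained`` cover only the axes with
    positive eigenvalues, the proportion denominator being the sum of
    positive eigenvalues.
    """

    labels: list[str]
    eigenvalues: np.ndarray
    coordinates: pd.DataFrame  # samples × positive axes
    proportion_explained: np.ndarray


def pcoa(labels: Sequence[str], distances: np.ndarray, atol: float = 1e-10) -> Ordination:
    """Principal coordinates analysis (classical multidimensional scaling).

    Double-centers −½D² (Gower centering) and eigendecomposes it. Axes
    are ordered by descending eigenvalue; eigenvalues within ``atol`` of
    zero (or negative) contribute no coordinates.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise DegenerateInputError("PCoA needs at least 2 samples")
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > atol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else np.array([])
    axes = [f"PCo{i + 1}" for i in range(int(positive.sum()))]
    return Ordination(
        labels=list(labels),
        eigenvalues=eigvals,
        coordinates=pd.DataFrame(coords, index=list(labels), columns=axes),
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------
# Permutation test of group separation (PERMANOVA-style)
# ---------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        m = idx.size
        if m > 1:
            block = d2[np.ix_(idx, idx)]
            ss_within += block[np.triu_indices(m, k=1)].sum() / m
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permutation_group_test(
    labels: Sequence[str],
    distances: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA-style permutation test of community separation.

    Partitions the squared-distance sum into among- and within-group
    components and compares the observed pseudo-F against ``n_perm``
    random relabelings. Returns ``(pseudo_F, p)`` with the add-one
    p estimator. Requires ≥ 2 groups, each of size ≥ 2, and
    ``n_perm ≥ 99``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    groups = np.asarray(groups)
    if len(groups) != len(labels):
        raise ValueError("one group label per sample is required")
    uniq, codes = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise DegenerateInputError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(counts < 2)]
        raise DegenerateInputError(f"group(s) with a single sample: {small}")
    d2 = np.asarray(distances, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniq)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(p)
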