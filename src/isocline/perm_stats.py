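"""Permutation-based group comparison (one-way PERMANOVA) and SIMPER.

PERMANOVA computes a pseudo-F directly from a distance matrix:

    SS_total  = Σ_{i<j} d²_ij / N
    SS_within = Σ_g Σ_{i<j ∈ g} d²_ij / n_g
    F = ((SS_total − SS_within)/(g − 1)) / (SS_within/(N − g))

and obtains significance by permuting group labels.  With Euclidean
distances on one variable this coincides exactly with the classical one-way
ANOVA F, which is the defensible reading of single-variable PERMANOVA runs.

SIMPER decomposes average Bray–Curtis dissimilarity between (or within)
groups into per-variable percentage contributions — here applied to the
matrix of posterior mean diet proportions from the mixing models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceSpec",
    "PermanovaResult",
    "SimperResult",
    "permanova",
    "pseudo_f",
    "simper",
]


@dataclass(frozen=True)
class DistanceSpec:
    """Distance configuration: metric and optional column standardization."""

    metric: str = "euclidean"
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.metric not in ("euclidean", "braycurtis"):
            raise ValueError("metric must be 'euclidean' or 'braycurtis'")


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class SimperResult:
    """Overall average Bray–Curtis dissimilarity (%) and per-variable shares (%)."""

    overall_average_dissimilarity: float
    contributions: tuple[float, ...]  # percentages summing to 100


def _distance_matrix(data: np.ndarray, spec: DistanceSpec) -> np.ndarray:
    if spec.metric == "braycurtis" and np.any(data < 0):
        raise ValueError("Bray–Curtis requires non-negative data")
    if spec.standardize:
        sd = data.std(axis=0, ddof=1)
        sd[~(sd > 0)] = 1.0
        data = (data - data.mean(axis=0)) / sd
    return squareform(pdist(data, metric=spec.metric))


def pseudo_f(dmat: np.ndarray, groups: Sequence) -> float:
    """Pseudo-F from a square distance matrix and group labels.

    Defined as 0 when the total sum of squares is zero (all points identical).
    """
    groups = np.asarray(groups)
    N = dmat.shape[0]
    labels = np.unique(groups)
    g = len(labels)
    d2 = dmat**2
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    if ss_total <= 0:
        return 0.0
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf
    return (ss_among / (g - 1)) / (ss_within / (N - g))


def permanova(
    data: np.ndarray,
    groups: Sequence,
    spec: DistanceSpec = DistanceSpec(),
    n_perm: int | str = 9999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with label-permutation significance.

    ``n_perm="exhaustive"`` enumerates every distinct label arrangement and
    reports the exact p (fraction of arrangements, observed included, whose F
    meets or exceeds the observed F).  Monte-Carlo mode uses the +1/+1 rule:
    p = (#{permuted F ≥ observed} + 1)/(n_perm + 1), seeded.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] != len(groups):
        data = data.T  # tolerate a 1-D row vector
    groups = np.asarray(groups)
    N = data.shape[0]
    if N < 3:
        raise ValueError("need at least 3 observations")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    dmat = _distance_matrix(data, spec)
    f_obs = pseudo_f(dmat, groups)

    if f_obs == 0.0:
        return PermanovaResult(0.0, 1.0, 0, tuple(int(c) for c in counts))

    tol = 1e-12 * max(1.0, abs(f_obs)) if math.isfinite(f_obs) else 0.0
    if n_perm == "exhaustive":
        hits = total = 0
        for perm in _distinct_permutations(groups):
            total += 1
            if pseudo_f(dmat, perm) >= f_obs - tol:
                hits += 1
        return PermanovaResult(
            f_obs, hits / total, total, tuple(int(c) for c in counts)
        )

    rng = np.random.default_rng(seed)
    hits = 0
    work = groups.copy()
    for _ in range(int(n_perm)):
        rng.shuffle(work)
        if pseudo_f(dmat, work) >= f_obs - tol:
            hits += 1
    p = (hits + 1) / (int(n_perm) + 1)
    return PermanovaResult(f_obs, p, int(n_perm), tuple(int(c) for c in counts))


def _distinct_permutations(labels: np.ndarray):
    """All distinct arrangements of a label multiset (small N only)."""
    seen = set()
    for perm in itertools.permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


# --------------------------------------------------------------------------
# SIMPER


def _bray_curtis_terms(xi: np.ndarray, xj: np.ndarray) -> tuple[np.ndarray, float]:
    denom = float((xi + xj).sum())
    if denom <= 0:
        raise ValueError("Bray–Curtis undefined for a pair of all-zero rows")
    return np.abs(xi - xj) / denom, denom


def simper(
    data: np.ndarray,
    groups: Sequence | None = None,
) -> SimperResult:
    """Similarity-percentage decomposition of Bray–Curtis dissimilarity.

    Two-group mode (``groups`` holds exactly two labels): averages over all
    between-group pairs.  Single-set mode (``groups is None``): averages over
    all pairs within the one set — the form used for the within-group
    dissimilarity of a single collection of consumers.

    Per-variable contribution of variable k in pair (i, j) is
    |x_ik − x_jk| / Σ_m (x_im + x_jm); contributions are averaged over pairs
    and normalized to percentages of the overall average dissimilarity.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if np.any(data < 0):
        raise ValueError("SIMPER requires non-negative data")
    if np.any(data.sum(axis=1) <= 0):
        raise ValueError("Bray–Curtis undefined for all-zero rows")

    if groups is None:
        pairs = list(itertools.combinations(range(data.shape[0]), 2))
    else:
        groups = np.asarray(groups)
        labels = np.unique(groups)
        if len(labels) != 2:
            raise ValueError("two-group mode needs exactly 2 labels")
        ia = np.flatnonzero(groups == labels[0])
        ib = np.flatnonzero(groups == labels[1])
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError("both groups must be non-empty")
        pairs = [(i, j) for i in ia for j in ib]
    if not pairs:
        raise ValueError("no pairs to average over")

    per_var = np.zeros(data.shape[1])
    for i, j in pairs:
        terms, _ = _bray_curtis_terms(data[i], data[j])
        per_var += terms
    per_var /= len(pairs)
    overall = float(per_var.sum())
    if overall <= 0:
        contrib = np.full(data.shape[1], 100.0 / data.shape[1])
    else:
        contrib = 100.0 * per_var / overall
    return SimperResult(
        overall_average_dissimilarity=100.0 * overall,
        contributions=tuple(float(c) for c in contrib),
    )
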