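"""Community-composition statistics for grouped metagenome samples.

The workflow mirrors the standard vegan-style beta-diversity recipe:
taxa count tables are Hellinger-transformed (square root of relative
abundance), pairwise Bray-Curtis dissimilarities are computed, and the
resulting distance matrix feeds a one-way PERMANOVA (pseudo-F with a
label-permutation p-value), average-linkage (UPGMA) clustering, and
non-metric multidimensional scaling (NMDS, Kruskal stress-1).

PERMANOVA follows Anderson's sums-of-squares decomposition computed
directly from the distance matrix:

    SS_total = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    SS_among = SS_total - SS_within
    F = (SS_among/(a-1)) / (SS_within/(N-a));  R^2 = SS_among/SS_total

with p = (1 + #{permuted F >= observed F}) / (n_permutations + 1), so
the p-value can never be zero.  An exact mode enumerates every label
permutation for small designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix


def _as_table(table: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        raise TypeError("abundance table must be a pandas DataFrame (samples x taxa)")
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance table has negative entries")
    if (values.sum(axis=1) <= 0).any():
        raise ValueError("abundance table has empty (all-zero) samples")
    return table


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of within-sample relative abundance.

    Each transformed row has unit sum of squares.
    """
    table = _as_table(table)
    values = table.to_numpy(dtype=float)
    rel = values / values.sum(axis=1, keepdims=True)
    return pd.DataFrame(np.sqrt(rel), index=table.index, columns=table.columns)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).  Apply after the
    Hellinger transform for the standard workflow.
    """
    table = _as_table(table)
    condensed = pdist(table.to_numpy(dtype=float), metric="braycurtis")
    if not np.isfinite(condensed).all():
        raise ValueError("Bray-Curtis undefined (a pair of all-zero samples?)")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    ss = 0.0
    for g, n_g in enumerate(sizes):
        m = codes == g
        ss += d2[np.ix_(m, m)].sum() / (2.0 * n_g)
    return ss


def permanova(
    dist: DistanceMatrix | np.ndarray,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` is a label sequence aligned with the matrix order (or a
    mapping/Series keyed by sample id when ``dist`` is a skbio
    DistanceMatrix).  ``n_permutations`` may be "exact" to enumerate
    all label orderings (designs of at most 8 samples), in which case
    p is the exact fraction of orderings with F >= observed.
    """
    if isinstance(dist, DistanceMatrix):
        ids = list(dist.ids)
        d = dist.data
        if isinstance(groups, (pd.Series, dict)):
            groups = [groups[i] for i in ids]
    else:
        d = np.asarray(dist, dtype=float)
    labels = pd.Categorical([str(g) for g in groups])
    codes = np.asarray(labels.codes, dtype=np.int64)
    n = d.shape[0]
    if len(codes) != n:
        raise ValueError("group labels do not match the distance matrix")
    a = len(labels.categories)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes, minlength=a)
    if (sizes == 0).any():
        raise ValueError("every group needs at least one sample")

    d2 = d.astype(float) ** 2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = _ss_within(d2, codes, sizes)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_among / (a - 1)) / (ss_within / (n - a)) if n > a else np.nan
    if ss_within == 0.0 and ss_among > 0.0:
        f_obs = np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0

    def f_of(perm_codes: np.ndarray) -> float:
        ssw = _ss_within(d2, perm_codes, sizes)
        ssa = ss_total - ssw
        if ssw == 0.0:
            return np.inf if ssa > 0 else np.nan
        return (ssa / (a - 1)) / (ssw / (n - a))

    if n_permutations == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to 8 samples")
        fs = np.array(
            [f_of(np.array(p, dtype=np.int64)) for p in itertools.permutations(codes)]
        )
        n_perm = math.factorial(n)
        p_value = float((fs >= f_obs).sum()) / n_perm
        return PermanovaResult(float(f_obs), float(r2), p_value, n_perm)

    n_perm = int(n_permutations)
    if n_perm < 1:
        raise ValueError("n_permutations must be at least 1")
    rng = np.random.default_rng(seed)
    # vectorized: SS_within for all permutations via indicator algebra
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    ssw_perm = np.zeros(n_perm)
    for g, n_g in enumerate(sizes):
        m = (perms == g).astype(float)  # (P, N)
        ssw_perm += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * n_g)
    ssa_perm = ss_total - ssw_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssa_perm / (a - 1)) / (ssw_perm / (n - a))
    f_perm[(ssw_perm == 0.0) & (ssa_perm > 0.0)] = np.inf
    p_value = (1.0 + float((f_perm >= f_obs).sum())) / (n_perm + 1.0)
    return PermanovaResult(float(f_obs), float(r2), float(p_value), n_perm)


@dataclass
class DendrogramResult:
    labels: list[str]
    linkage_matrix: np.ndarray  # scipy hierarchical-clustering encoding
    merge_heights: np.ndarray  # ultrametric node heights (distance / 2)
    newick: str


def average_linkage(dist: DistanceMatrix) -> DendrogramResult:
    """UPGMA (average-linkage) clustering of a distance matrix.

    Leaves are ordered lexicographically before clustering so that
    tie-breaking is deterministic.  Merge heights are ultrametric node
    heights (half the average linkage distance); the Newick string
    carries branch lengths derived from them.
    """
    if len(dist.ids) < 2:
        raise ValueError("need at least two samples to cluster")
    order = sorted(range(len(dist.ids)), key=lambda i: str(dist.ids[i]))
    labels = [str(dist.ids[i]) for i in order]
    d = dist.data[np.ix_(order, order)]
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2] / 2.0

    root = to_tree(Z)

    def height(node) -> float:
        return 0.0 if node.is_leaf() else heights[node.id - len(labels)]

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        h = height(node)
        parts = [
            f"{newick(child)}:{h - height(child):.10g}"
            for child in (node.left, node.right)
        ]
        return "(" + ",".join(parts) + ")"

    return DendrogramResult(labels, Z, heights, newick(root) + ";")


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1
    converged: bool


def kruskal_stress1(dist: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against observed dissimilarities.

    Disparities are the isotonic (monotone) regression of the embedded
    distances on the observed dissimilarity ranks.
    """
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(dist.shape[0], k=1)
    obs = dist[iu]
    emb = squareform(
        np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)), checks=False
    )
    disp = IsotonicRegression().fit_transform(obs, emb)
    denom = float((emb**2).sum())
    if denom == 0:
        return float("inf")
    return float(np.sqrt(((disp - emb) ** 2).sum() / denom))


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 8,
    max_iter: int = 300,
    seed: int | None = None,
) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Optimisation is SMACOF iterative majorization with monotone
    regression; one restart is initialised from the classical
    (metric) scaling solution and the rest from seeded random
    configurations, keeping the embedding with the lowest stress-1.
    """
    from sklearn.manifold import smacof

    if k < 1:
        raise ValueError("k must be at least 1")
    d = np.asarray(dist.data, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    n = d.shape[0]

    # classical-scaling initialisation: double-centred Gram eigenvectors
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(gram)
    top = np.argsort(vals)[::-1][:k]
    init = vecs[:, top] * np.sqrt(np.maximum(vals[top], 0.0))

    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    inits = [init] + [rng.normal(size=(n, k)) for _ in range(max(0, n_restarts - 1))]
    for start in inits:
        coords, _ = smacof(
            d,
            metric=False,
            n_components=k,
            init=start,
            n_init=1,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31)),
            normalized_stress=True,
        )
        s1 = kruskal_stress1(d, coords)
        if s1 < best_stress:
            best_coords, best_stress = coords, s1
    cols = [f"NMDS{i + 1}" for i in range(k)]
    coords_df = pd.DataFrame(best_coords, index=[str(i) for i in dist.ids], columns=cols)
    return NMDSResult(coords_df, best_stress, converged=np.isfinite(best_stress))
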