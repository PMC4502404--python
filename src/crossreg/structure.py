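"""Sample-structure diagnostics.

PCA with covariate association, distance matrices and neighbor-joining
trees, coefficient-of-variation and within-group distance-homogeneity
statistics, and the beta-value methylation-state classification.  These
are the diagnostics used to ask whether samples separate by species or
tissue, and whether reprogrammed lines are more homogeneous than their
somatic precursors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError


@dataclass
class Embedding:
    """PCA result: sample x component scores, loadings and variance
    fractions (nonincreasing, summing to <= 1)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    centered: bool = True
    scaled: bool = False


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> Embedding:
    """Principal components of a feature x sample matrix via SVD.

    Features are centered (and optionally unit-scaled) across samples;
    zero-variance features are dropped with a warning.  Each component's
    sign is fixed by making its largest-magnitude loading positive.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    x = matrix.to_numpy(float)
    var = x.var(axis=1)
    if (var == 0).any():
        warnings.warn(f"dropping {int((var == 0).sum())} zero-variance feature(s)",
                      stacklevel=2)
        matrix = matrix.loc[var > 0]
        x = matrix.to_numpy(float)
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    if scale:
        x = x / x.std(axis=1, ddof=1, keepdims=True)
    # samples as rows for the decomposition
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    k = min(matrix.shape[1] - 1, matrix.shape[0])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for comp in range(k):
        j = int(np.argmax(np.abs(vt[comp])))
        if vt[comp, j] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    total_var = (x**2).sum()
    var_explained = s**2 / total_var if total_var > 0 else np.zeros(k)
    comps = [f"PC{i + 1}" for i in range(k)]
    return Embedding(
        scores=pd.DataFrame(u * s, index=matrix.columns, columns=comps),
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comps),
        variance_explained=var_explained,
        centered=center,
        scaled=scale,
    )


def pc_covariate_association(scores: pd.Series, factor: pd.Series) -> float:
    """One-way linear-model F-test p-value of PC scores on a factor."""
    factor = pd.Series(factor).loc[scores.index]
    groups = [scores[factor == lv].to_numpy() for lv in factor.unique()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 levels each with >= 2 samples")
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # identical scores in every group
        return 1.0
    return float(p)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray
    metric: str

    def within_group(self, members: list[str]) -> np.ndarray:
        """All pairwise distances among the given samples."""
        idx = [self.labels.index(m) for m in members]
        return np.array(
            [self.matrix[i, j] for i, j in itertools.combinations(idx, 2)]
        )


def distance_matrix(matrix: pd.DataFrame, metric: str = "manhattan") -> DistanceMatrix:
    """Pairwise distances between samples (columns) of a feature x sample
    matrix.  Supported metrics: manhattan, euclidean."""
    if matrix.isna().any().any():
        raise ValidationError("distance matrix input contains NaN")
    scipy_metric = {"manhattan": "cityblock", "euclidean": "euclidean"}.get(metric)
    if scipy_metric is None:
        raise ValidationError(f"unknown metric {metric!r}")
    d = squareform(pdist(matrix.to_numpy(float).T, metric=scipy_metric))
    return DistanceMatrix(list(matrix.columns), d, metric)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as newick text.

    Standard Q-criterion agglomeration; ties are broken by the
    lexicographically lowest pair of clade labels (a clade is labelled by
    its smallest member taxon), making the output deterministic.  Branch
    lengths may be negative and are reported as computed.  The tree is
    unrooted (trifurcating root node).
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    # active nodes: id -> (newick string, canonical label)
    d = {i: {j: float(dm.matrix[i, j]) for j in range(n0) if j != i}
         for i in range(n0)}
    newick = {i: str(lab) for i, lab in enumerate(dm.labels)}
    canon = {i: str(lab) for i, lab in enumerate(dm.labels)}
    next_id = n0

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(d) > 3:
        nodes = sorted(d)
        n = len(nodes)
        r = {i: sum(d[i][j] for j in d[i]) for i in nodes}
        best = None
        best_q = np.inf
        for a, b in itertools.combinations(nodes, 2):
            q = (n - 2) * d[a][b] - r[a] - r[b]
            key = tuple(sorted((canon[a], canon[b])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and best is not None and key < best[1]
            ):
                best_q = q
                best = ((a, b), key)
        (a, b), _ = best  # type: ignore[misc]
        dab = d[a][b]
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        new = next_id
        next_id += 1
        d[new] = {}
        for k in nodes:
            if k in (a, b):
                continue
            dk = 0.5 * (d[a][k] + d[b][k] - dab)
            d[new][k] = dk
            d[k][new] = dk
            del d[k][a], d[k][b]
        del d[a], d[b]
        first, second = sorted((a, b), key=lambda i: canon[i])
        lens = {a: la, b: lb}
        newick[new] = (
            f"({newick[first]}:{fmt(lens[first])},{newick[second]}:{fmt(lens[second])})"
        )
        canon[new] = min(canon[a], canon[b])
        del newick[a], newick[b], canon[a], canon[b]

    i, j, k = sorted(d, key=lambda x: canon[x])
    li = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    lj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    lk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    return (
        f"({newick[i]}:{fmt(li)},{newick[j]}:{fmt(lj)},{newick[k]}:{fmt(lk)});"
    )


def sample_cv(values) -> float:
    """Coefficient of variation: sample standard deviation over mean."""
    values = np.asarray(values, float)
    mean = values.mean()
    if mean <= 0:
        raise ValidationError("CV requires a positive mean")
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / mean)


def compare_group_distances(
    dm: DistanceMatrix, group_a: list[str], group_b: list[str]
) -> tuple[float, float]:
    """Compare within-group pairwise distance distributions of two
    disjoint sample groups.

    Collects all within-group pairwise distances for each group and runs
    a two-sided Mann-Whitney U test (exact by enumeration of group
    assignments when feasible, asymptotic otherwise).  Returns ``(U, p)``.
    """
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("each group needs >= 3 samples")
    da = dm.within_group(group_a)
    db = dm.within_group(group_b)
    u = _rank_u(da, db)
    m, n = len(da), len(db)
    from math import comb

    if comb(m + n, m) <= 200_000:
        pooled = np.concatenate([da, db])
        center = m * n / 2.0
        obs_dev = abs(u - center)
        hits = total = 0
        for idx in itertools.combinations(range(m + n), m):
            mask = np.zeros(m + n, bool)
            mask[list(idx)] = True
            u_perm = _rank_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - center) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        _, p = stats.mannwhitneyu(da, db, alternative="two-sided",
                                  method="asymptotic")
    return float(u), float(p)


def _rank_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of sample x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def beta_state(beta):
    """Classify methylation beta values into hypo / hemi / hyper states.

    hyper if beta >= 0.8; hemi if 0.2 < beta < 0.8 (strict); hypo if
    beta <= 0.2.
    """
    arr = np.asarray(beta, float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValidationError("beta values must lie in [0, 1]")
    out = np.where(arr >= 0.8, "hyper", np.where(arr > 0.2, "hemi", "hypo"))
    if np.isscalar(beta) or arr.ndim == 0:
        return str(out)
    return out
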