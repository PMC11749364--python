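"""Weighted co-editing network: adjacency, TOM, modules, eigen-profiles.

The network follows the weighted-correlation-network recipe: unsigned
adjacency a_ij = |cor(x_i, x_j)|^beta with soft threshold beta = 12, a
topological overlap transformation, average-linkage clustering of 1 - TOM,
a static branch cut with a module-size floor and eigen-profile-based
reassignment of small-branch sites (a documented simplification of the
dynamic hybrid tree cut), merging of modules whose eigen-profiles correlate
above 1 - mergeCutHeight, and module membership MM(i) = cor(x_i, E^q) with
hubs at MM > 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Heights scanned by the adaptive branch cut (ascending; the lowest height
#: achieving the maximal number of large branches wins).
CUT_GRID = np.arange(0.95, 0.998, 0.0025)


@dataclass
class NetworkParams:
    """Tunable parameters of the co-editing network."""

    beta: float = 12.0
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    hub_mm_min: float = 0.9
    #: static dendrogram cut; None scans CUT_GRID and keeps the lowest
    #: height yielding the most branches >= min_module_size
    cut_height: float | None = None
    #: membership floor for the eigen-refinement passes; None uses the
    #: 99% null critical |r| for the sample count
    assign_cor_min: float | None = None
    refine_max_iter: int = 20

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if not 0 < self.hub_mm_min < 1:
            raise ValueError("hub_mm_min must be in (0, 1)")


@dataclass
class CoEditingModule:
    module_id: int
    members: list[str]
    eigen_profile: np.ndarray
    membership: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    hubs: list[str] = field(default_factory=list)


def build_matrix(site_levels: pd.DataFrame, require_all: bool = True
                 ) -> pd.DataFrame:
    """Pivot an interrogation frame into a sites x samples level matrix.

    With ``require_all`` only sites qualified in every sample are retained
    (the construction used for the common-site network).
    """
    qual = site_levels.pivot(index="site", columns="sample_id",
                             values="qualified").fillna(False)
    levels = site_levels.pivot(index="site", columns="sample_id",
                               values="level")
    if levels.shape[1] < 3:
        raise ValueError("need at least 3 samples for a co-editing network")
    if require_all:
        keep = qual.all(axis=1)
        levels = levels[keep]
    return levels


def adjacency(matrix: pd.DataFrame, params: NetworkParams | None = None
              ) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta (diagonal 1).

    Zero-variance rows are dropped with a warning before correlation.
    """
    p = params or NetworkParams()
    X = matrix.to_numpy(float)
    var = X.var(axis=1)
    keep = var > 0
    if not keep.all():
        dropped = matrix.index[~keep].tolist()
        logger.warning("dropping %d zero-variance profiles: %s...",
                       len(dropped), dropped[:5])
        matrix = matrix.loc[keep]
        X = matrix.to_numpy(float)
    cor = np.corrcoef(X)
    cor = np.clip(cor, -1.0, 1.0)
    adj = np.abs(cor) ** p.beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.index)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with k_i the connectivity sum excluding the diagonal; TOM_ii = 1.
    The shared-neighbor sum excludes u in {i, j}.
    """
    A = adj.to_numpy(float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # includes u = i and u = j terms, both zero off-diagonal
    # A has zero diagonal so (A@A)_ij = sum_u a_iu a_uj excludes u=i (a_ii=0)
    # and u=j (a_jj=0) automatically for i != j.
    num = shared + A
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def _null_cor_critical(n_samples: int, q: float = 0.95) -> float:
    """Two-sided critical |r| at level 1-q for independent profiles."""
    df = n_samples - 2
    t = stats.t.ppf(0.5 + q / 2, df)
    return float(t / np.sqrt(t * t + df))


def module_eigen(matrix: pd.DataFrame, labels: pd.Series
                 ) -> dict[int, np.ndarray]:
    """First principal component (eigen-profile) per module.

    Member profiles are standardised across samples; the unit-norm first
    right singular vector is sign-oriented so the mean correlation with
    member profiles is positive. Label 0 (unassigned) has no eigen.
    """
    eigens: dict[int, np.ndarray] = {}
    for mod in sorted(set(labels) - {0}):
        members = labels.index[labels == mod]
        X = matrix.loc[members].to_numpy(float)
        Z = _standardize(X)
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        e = vt[0]
        cors = Z @ e / (np.linalg.norm(Z, axis=1) * np.linalg.norm(e) + 1e-300)
        if cors.mean() < 0:
            e = -e
        eigens[mod] = e / np.linalg.norm(e)
    return eigens


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def cluster_modules(diss: pd.DataFrame, matrix: pd.DataFrame,
                    params: NetworkParams | None = None) -> pd.Series:
    """Average-linkage clustering of 1-TOM with a static cut and size floor.

    Branches cut at ``cut_height`` with >= ``min_module_size`` members
    become modules. Two eigen-profile refinement passes follow: members
    whose correlation with their branch eigen falls below ``prune_cor_min``
    (default: the 95% null critical |r| for the sample count) are released
    — average linkage chains weakly attached sites into branches — and
    released or small-branch sites are assigned to the module whose eigen
    they correlate with most strongly when that clears the stricter
    ``reassign_cor_min`` (default: the 99% critical value; adding a site
    demands stronger evidence than keeping one), else stay unassigned
    (label 0). Labels are ordered by decreasing module size (ties:
    smallest member key) and are invariant to site order.
    """
    p = params or NetworkParams()
    sites = diss.index
    n = len(sites)
    if n < p.min_module_size:
        logger.warning("fewer sites (%d) than min_module_size", n)
        return pd.Series(0, index=sites)
    D = diss.to_numpy(float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    if p.cut_height is not None:
        raw = fcluster(Z, t=p.cut_height, criterion="distance")
    else:
        best_raw, best_count = None, -1
        for t in CUT_GRID:
            cand = fcluster(Z, t=t, criterion="distance")
            counts = np.bincount(cand)
            n_big = int((counts >= p.min_module_size).sum())
            if n_big > best_count:
                best_raw, best_count = cand, n_big
        raw = best_raw
    raw_labels = pd.Series(raw, index=sites)
    sizes = raw_labels.value_counts()
    big = [int(c) for c in sizes.index[sizes >= p.min_module_size]]
    labels = pd.Series(0, index=sites, dtype=int)
    for new, old in enumerate(
            sorted(big, key=lambda c: (-int(sizes[c]),
                                       min(sites[raw_labels == c]))),
            start=1):
        labels[raw_labels == old] = new
    if not big:
        return labels
    labels = _refine_labels(matrix, labels, p)
    return _relabel_by_size(labels)


def _refine_labels(matrix: pd.DataFrame, labels: pd.Series,
                   p: NetworkParams) -> pd.Series:
    """Iterative eigen-based membership refinement with hysteresis.

    Alternates eigen-profile estimation with reassignment of every site to
    the module whose eigen it correlates with most strongly, until stable.
    A site keeps its current module while |r| clears the keep floor (the
    95% null critical value for the sample count, or ``assign_cor_min``);
    a site joins a new module only when |r| clears the stricter join floor
    (the 99% critical value) — admitting a site demands stronger evidence
    than retaining one, which both limits background absorption and
    prevents erosion cascades. This releases sites chained into a branch
    without support and recovers members the branch cut missed.
    """
    n_samples = matrix.shape[1]
    keep_floor = (p.assign_cor_min if p.assign_cor_min is not None
                  else _null_cor_critical(n_samples, 0.95))
    join_floor = max(keep_floor, _null_cor_critical(n_samples, 0.99))
    X = matrix.to_numpy(float)
    Z = _standardize(X)
    norm = np.linalg.norm(Z, axis=1)
    norm[norm == 0] = 1.0
    for _ in range(p.refine_max_iter):
        eigens = module_eigen(matrix, labels)
        if not eigens:
            break
        mods = sorted(eigens)
        E = np.array([eigens[m] / np.linalg.norm(eigens[m]) for m in mods])
        cors = np.abs((Z / norm[:, None]) @ E.T)  # |cor| since eigens centred
        best_idx = cors.argmax(axis=1)
        best_mod = np.array(mods)[best_idx]
        best_cor = cors.max(axis=1)
        cur = labels.to_numpy()
        floor = np.where(best_mod == cur, keep_floor, join_floor)
        new = np.where(best_cor >= floor, best_mod, 0)
        # a current member below the join floor for its best module but
        # above the keep floor for its own stays put
        mod_pos = {m: i for i, m in enumerate(mods)}
        for i, site_mod in enumerate(cur):
            if new[i] == 0 and site_mod != 0:
                own = cors[i, mod_pos[site_mod]]
                if own >= keep_floor:
                    new[i] = site_mod
        new_labels = pd.Series(new, index=labels.index)
        if new_labels.equals(labels):
            break
        labels = new_labels
    return labels


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != 0].value_counts()
    order = sorted(sizes.index,
                   key=lambda c: (-int(sizes[c]),
                                  min(labels.index[labels == c])))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    return labels.map(mapping)


def merge_modules(matrix: pd.DataFrame, labels: pd.Series,
                  params: NetworkParams | None = None) -> pd.Series:
    """Merge modules whose eigen-profiles cluster below merge_cut_height.

    Average-linkage clustering of modules on 1 - cor(E_p, E_q); clusters
    joined below the height are merged and eigens recomputed, iterating to
    a fixpoint so a second call changes nothing.
    """
    p = params or NetworkParams()
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eigens = module_eigen(matrix, labels)
        E = np.array([eigens[m] for m in mods])
        cor = np.clip(np.corrcoef(E), -1.0, 1.0)
        D = 1.0 - cor
        np.fill_diagonal(D, 0.0)
        Z = average(squareform(D, checks=False))
        groups = fcluster(Z, t=p.merge_cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        remap = {}
        for mod, grp in zip(mods, groups):
            remap.setdefault(grp, []).append(mod)
        for grp, members in remap.items():
            target = min(members)
            for m in members:
                labels[labels == m] = target
    return _relabel_by_size(labels)


def module_membership(matrix: pd.DataFrame, labels: pd.Series,
                      eigens: dict[int, np.ndarray],
                      params: NetworkParams | None = None
                      ) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """MM = cor(site profile, module eigen) for every site x module.

    Hubs are own-module sites with MM > ``hub_mm_min``. Zero-variance
    profiles yield NaN and are excluded from hub calls (logged).
    """
    p = params or NetworkParams()
    X = matrix.to_numpy(float)
    mm = pd.DataFrame(index=matrix.index,
                      columns=sorted(eigens), dtype=float)
    for mod, e in eigens.items():
        for site, x in zip(matrix.index, X):
            mm.loc[site, mod] = _pearson(x, e)
    hubs: dict[int, list[str]] = {m: [] for m in eigens}
    for site in matrix.index:
        mod = int(labels[site])
        if mod == 0:
            continue
        val = mm.loc[site, mod]
        if np.isnan(val):
            logger.warning("zero-variance profile %s excluded from MM", site)
            continue
        if val > p.hub_mm_min:
            hubs[mod].append(site)
    return mm, hubs


class CoEditingNetwork:
    """Fit-style wrapper over the network pipeline.

    Parameters mirror :class:`NetworkParams`. After :meth:`fit` on a sites
    x samples level matrix the fitted attributes are ``labels_`` (module
    label per site, 0 = unassigned), ``modules_`` (list of
    :class:`CoEditingModule`), ``membership_`` (sites x modules MM frame)
    and ``tom_``.
    """

    def __init__(self, beta: float = 12.0, min_module_size: int = 30,
                 merge_cut_height: float = 0.25, hub_mm_min: float = 0.9,
                 cut_height: float | None = None,
                 assign_cor_min: float | None = None) -> None:
        self.beta = beta
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.hub_mm_min = hub_mm_min
        self.cut_height = cut_height
        self.assign_cor_min = assign_cor_min

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "beta", "min_module_size", "merge_cut_height", "hub_mm_min",
            "cut_height", "assign_cor_min")}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _network_params(self) -> NetworkParams:
        return NetworkParams(beta=self.beta,
                             min_module_size=self.min_module_size,
                             merge_cut_height=self.merge_cut_height,
                             hub_mm_min=self.hub_mm_min,
                             cut_height=self.cut_height,
                             assign_cor_min=self.assign_cor_min)

    def fit(self, matrix: pd.DataFrame) -> "CoEditingNetwork":
        params = self._network_params()
        adj = adjacency(matrix, params)
        matrix = matrix.loc[adj.index]  # zero-variance rows dropped
        T = tom(adj)
        diss = 1.0 - T
        labels = cluster_modules(diss, matrix, params)
        labels = merge_modules(matrix, labels, params)
        eigens = module_eigen(matrix, labels)
        mm, hubs = module_membership(matrix, labels, eigens, params)
        self.tom_ = T
        self.labels_ = labels
        self.membership_ = mm
        self.modules_ = [
            CoEditingModule(
                module_id=mod,
                members=list(labels.index[labels == mod]),
                eigen_profile=eigens[mod],
                membership=mm[mod],
                hubs=hubs[mod])
            for mod in sorted(eigens)]
        return self

    def fit_predict(self, matrix: pd.DataFrame) -> pd.Series:
        return self.fit(matrix).labels_
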