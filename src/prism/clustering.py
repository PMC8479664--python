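"""Model-based agglomerative clustering of single-cell profiles with BIC.

When no cell-type labels are available, a binary composition over the
reference cells is built up agglomeratively under the same scaled-Poisson
model used for deconvolution: every cell starts as its own component with
profile (x, t) fitted by the closed-form M-steps, and at each step the pair
of components whose merge loses the least model log-likelihood is joined,
with the merged profile refitted.  Agglomeration is deterministic given the
input, which makes it considerably more stable than iterative multi-start
clustering, and scoring every cut of the merge path with the Bayesian
information criterion selects the number of components.

Likelihoods here use the normalized log-density convention
(:func:`prism.model.scaled_poisson_logpdf`): clusterings with different
precisions must be compared on density scale, under which a merge can only
lose likelihood and BIC comparisons are meaningful.

Cells' scale factors (sequencing depth) are estimated first with the
trimmed common-profile estimator, or supplied by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import CellLabels, CountMatrix, ValidationError, T_MIN, T_MAX
from .model import scaled_poisson_logpdf
from .scalefactors import estimate_scale_factors

__all__ = ["ClusterTree", "cluster_profiles", "bic"]

logger = logging.getLogger("prism")


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, ``-2 loglik + n_params ln(n_obs)``."""
    if n_obs < 1:
        raise ValidationError("n_obs must be >= 1")
    return -2.0 * float(loglik) + n_params * float(np.log(n_obs))


@dataclass
class ClusterTree:
    """Agglomerative merge history with per-cut likelihood and BIC.

    ``merges`` lists ``(node_a, node_b, merged_node, loglik_after_merge)``
    in merge order; node ids < number of leaves are leaves, higher ids are
    merged nodes.  ``leaves`` gives the member unit indices of each leaf
    (singletons unless duplicate collapsing or coarse pre-merging seeded
    larger leaves).  ``bic_by_k`` maps each cluster count on the merge path
    to its BIC; ``chosen_k`` minimizes it (smallest k on ties).
    """

    merges: list[tuple[int, int, int, float]]
    leaves: list[np.ndarray]
    bic_by_k: dict[int, float]
    loglik_by_k: dict[int, float]
    chosen_k: int
    labels_at_chosen_k: CellLabels
    unit_ids: list[str] = field(default_factory=list)

    def labels_at(self, k: int) -> CellLabels:
        """Cut the merge path at ``k`` clusters and emit labels."""
        members = _cut(self.leaves, self.merges, k)
        return _members_to_labels(members, self.unit_ids)


def _members_to_labels(members: list[np.ndarray], unit_ids) -> CellLabels:
    # name clusters C1.. in order of their first member unit
    members = sorted(members, key=lambda c: int(c.min()))
    lab = [""] * len(unit_ids)
    names = []
    for ci, cells in enumerate(members, start=1):
        name = f"C{ci}"
        names.append(name)
        for j in cells:
            lab[int(j)] = name
    return CellLabels(list(unit_ids), lab, names)


def _cut(leaves, merges, k: int) -> list[np.ndarray]:
    n_leaves = len(leaves)
    if not (1 <= k <= n_leaves):
        raise ValidationError(f"cannot cut tree with {n_leaves} leaves at {k}")
    members = {i: leaves[i] for i in range(n_leaves)}
    for a, b, new, _ll in merges[: n_leaves - k]:
        members[new] = np.concatenate([members.pop(a), members.pop(b)])
    return list(members.values())


class _Cluster:
    __slots__ = ("cells", "x", "t", "ll", "g")

    def __init__(self, cells, x, t, ll, g):
        self.cells, self.x, self.t, self.ll, self.g = cells, x, t, ll, g


def _fit_cluster(Z, G, cells, t_min, t_max) -> _Cluster:
    """Closed-form profile fit of one component over its member cells."""
    sub = Z[:, cells]
    gsub = G[cells]
    g = float(gsub.sum())
    x = sub.sum(axis=1) / g
    lam = x[:, None] * gsub[None, :]
    lam_sum = x * g
    resid2 = ((sub - lam) ** 2).sum(axis=1)
    t = np.ones_like(x)
    info = lam_sum > 0
    with np.errstate(divide="ignore"):
        est = np.where(resid2 > 0, lam_sum / np.maximum(resid2, 1e-300),
                       np.inf)
    t[info] = np.clip(est[info], t_min, t_max)
    ll = float(scaled_poisson_logpdf(sub, lam, t[:, None]).sum())
    return _Cluster(np.asarray(cells, dtype=int), x, t, ll, g)


def _merge_fit(Z, G, a: _Cluster, b: _Cluster, t_min, t_max) -> _Cluster:
    return _fit_cluster(
        Z, G, np.concatenate([a.cells, b.cells]), t_min, t_max
    )


def _collapse_duplicates(Z) -> list[np.ndarray]:
    """Group exactly identical count columns into seed leaves."""
    _, inv = np.unique(Z.T, axis=0, return_inverse=True)
    groups: dict[int, list[int]] = {}
    for j, gidx in enumerate(inv):
        groups.setdefault(int(gidx), []).append(j)
    # leaves ordered by first member for determinism
    ordered = sorted(groups.values(), key=lambda c: c[0])
    return [np.asarray(c, dtype=int) for c in ordered]


def _coarse_premerge(Z, G, leaves, target: int, cap: int, t_min, t_max):
    """Reduce the number of starting clusters to ``target`` by greedy
    likelihood merges restricted to each cluster's ``cap`` nearest
    neighbours (cosine similarity of log1p mean profiles).  A documented
    approximation used only above the exact-pass size threshold."""
    merges: list[tuple[int, int, int, float]] = []
    clusters = {
        i: _fit_cluster(Z, G, cells, t_min, t_max)
        for i, cells in enumerate(leaves)
    }
    next_id = len(leaves)
    while len(clusters) > target:
        ids = sorted(clusters)
        prof = np.array(
            [np.log1p(clusters[i].x) for i in ids]
        )
        norm = np.linalg.norm(prof, axis=1)
        sim = (prof @ prof.T) / np.maximum(
            np.outer(norm, norm), 1e-300
        )
        np.fill_diagonal(sim, -np.inf)
        best = None
        for ai, i in enumerate(ids):
            nbr = np.argsort(-sim[ai], kind="stable")[:cap]
            for bi in nbr:
                j = ids[bi]
                if j <= i:
                    continue
                m = _merge_fit(Z, G, clusters[i], clusters[j], t_min, t_max)
                delta = m.ll - clusters[i].ll - clusters[j].ll
                key = (delta, -i, -j)
                if best is None or key > best[0]:
                    best = (key, i, j, m)
        _, i, j, m = best
        total_after = (
            sum(c.ll for c in clusters.values())
            - clusters[i].ll - clusters[j].ll + m.ll
        )
        del clusters[i], clusters[j]
        clusters[next_id] = m
        merges.append((i, j, next_id, total_after))
        next_id += 1
    return clusters, merges, next_id


def cluster_profiles(
    sc: CountMatrix,
    scales: np.ndarray | str | None = None,
    alpha: float = 0.5,
    t_min: float = T_MIN,
    t_max: float = T_MAX,
    micro_cluster_threshold: int = 2000,
    neighbor_cap: int = 20,
) -> ClusterTree:
    """Agglomeratively cluster reference cells under the readout model.

    Parameters
    ----------
    sc
        Genes x cells counts.
    scales
        Per-cell scale factors.  By default gauge-fixed column totals are
        used: the cells being clustered span *multiple* phenotypes, which
        violates the common-profile assumption of the trimmed estimator
        (whose retained set then degenerates to near-zero-count genes).
        Pass ``"trimmed"`` to use
        :func:`prism.scalefactors.estimate_scale_factors` (at ``alpha``)
        anyway, or an explicit positive array.
    micro_cluster_threshold
        Above this many starting clusters (after exact-duplicate
        collapsing) a coarse capped-neighbour merge pass reduces the count
        before the exact all-pairs agglomeration.

    Returns
    -------
    ClusterTree
        Full merge history, BIC per cluster count, the BIC-optimal cut and
        its labels (usable directly as a reference labelling for the
        decomposition).
    """
    Z = sc.values
    m, n = Z.shape
    if n < 1:
        raise ValidationError("no cells")
    if scales is None:
        totals = Z.sum(axis=0)
        if np.any(totals <= 0):
            raise ValidationError(
                "cells with zero counts have no scale; remove them first"
            )
        G = totals / np.exp(np.mean(np.log(totals)))
    elif isinstance(scales, str) and scales == "trimmed":
        fit = estimate_scale_factors(
            sc, alpha=alpha, t_min=t_min, t_max=t_max
        )
        G = fit.G
        if np.any(~np.isfinite(G)):
            raise ValidationError(
                "cells with zero counts have no scale; remove them first"
            )
    else:
        G = np.asarray(scales, dtype=float)
        if G.shape != (n,) or np.any(~np.isfinite(G)) or np.any(G <= 0):
            raise ValidationError("scales must be positive, one per cell")

    # above the exact-pass threshold, pre-seed micro-clusters by collapsing
    # exactly duplicated columns (a zero-loss merge under equal scales)
    if n > micro_cluster_threshold:
        leaves = _collapse_duplicates(Z)
    else:
        leaves = [np.array([j]) for j in range(n)]
    if n == 1:
        only = _fit_cluster(Z, G, np.array([0]), t_min, t_max)
        labels = _members_to_labels([np.array([0])], sc.unit_ids)
        b1 = bic(only.ll, 2 * m + n, n * m)
        return ClusterTree(
            merges=[], leaves=leaves, bic_by_k={1: b1},
            loglik_by_k={1: only.ll}, chosen_k=1,
            labels_at_chosen_k=labels, unit_ids=list(sc.unit_ids),
        )

    merges: list[tuple[int, int, int, float]] = []
    loglik_by_k: dict[int, float] = {}
    if len(leaves) > micro_cluster_threshold:
        clusters, merges, next_id = _coarse_premerge(
            Z, G, leaves, micro_cluster_threshold, neighbor_cap,
            t_min, t_max,
        )
        for step, (_, _, _, ll_after) in enumerate(merges):
            loglik_by_k[len(leaves) - step - 1] = ll_after
    else:
        clusters = {
            i: _fit_cluster(Z, G, cells, t_min, t_max)
            for i, cells in enumerate(leaves)
        }
        next_id = len(leaves)

    total_ll = sum(c.ll for c in clusters.values())
    loglik_by_k[len(clusters)] = total_ll

    # cache merged fits per candidate pair; refresh pairs involving new ids
    cache: dict[tuple[int, int], _Cluster] = {}

    def _candidate(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            cache[key] = _merge_fit(
                Z, G, clusters[key[0]], clusters[key[1]], t_min, t_max
            )
        return key, cache[key]

    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai, i in enumerate(ids):
            for j in ids[ai + 1:]:
                key, mfit = _candidate(i, j)
                delta = mfit.ll - clusters[i].ll - clusters[j].ll
                order = (delta, -i, -j)  # ties: smaller (i, j) wins
                if best is None or order > best[0]:
                    best = (order, i, j, mfit)
        _, i, j, mfit = best
        total_ll += best[0][0]
        del clusters[i], clusters[j]
        for key in [k for k in cache if i in k or j in k]:
            del cache[key]
        clusters[next_id] = mfit
        merges.append((i, j, next_id, total_ll))
        loglik_by_k[len(clusters)] = total_ll
        next_id += 1

    bic_by_k = {
        k: bic(ll, k * 2 * m + n, n * m) for k, ll in loglik_by_k.items()
    }
    chosen_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    members = _cut(leaves, merges, chosen_k)
    labels = _members_to_labels(members, sc.unit_ids)
    logger.info(
        "agglomeration over %d leaves: BIC selects k=%d",
        len(leaves), chosen_k,
    )
    return ClusterTree(
        merges=merges,
        leaves=leaves,
        bic_by_k=bic_by_k,
        loglik_by_k=loglik_by_k,
        chosen_k=chosen_k,
        labels_at_chosen_k=labels,
        unit_ids=list(sc.unit_ids),
    )
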