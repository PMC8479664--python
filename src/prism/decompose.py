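"""Joint decomposition of bulk samples against a single-cell reference.

Each bulk sample (optionally with replicates that share expression profiles
but have their own composition) is fitted jointly with the labelled
reference under the scaled-Poisson model: the expression profiles (X, T)
are SHARED between the reference and bulk blocks, so the bulk adapts the
profiles while the reference anchors them.  The fit is a block-coordinate
ascent on the joint quasi-log-likelihood:

* E: expected allocation of each observed count over cell types
  (proportional rule; damped by a line search if a step would reduce the
  objective, which keeps the recorded trace monotone);
* M: closed-form updates of X (pooled ratio), of each bulk composition
  jointly with its scale (separable concave maximizer), of the reference
  scale factors, and a moment-matching precision update accepted entrywise
  only where it does not reduce the objective.

A gauge convention (geometric mean of reference scale factors = 1) resolves
the X <-> G scale ambiguity so fitted profiles are comparable across
samples and runs.  The fit is deterministic: initialization is data-driven
and no step draws random numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import (
    CellLabels,
    CountMatrix,
    DecompositionResult,
    ValidationError,
    T_MIN,
    T_MAX,
)
from .model import allocation_matrix, scaled_poisson_loglik

__all__ = ["FitOptions", "fit_joint", "allocate_bulk", "decompose_cohort",
           "CohortResult"]

logger = logging.getLogger("prism")


@dataclass
class FitOptions:
    """Tunable settings of the joint fit.

    ``tol`` is the relative change of the joint quasi-log-likelihood below
    which the fit stops; ``free_reference`` lets the reference compositions
    vary instead of being preset one-hot from the labels;
    ``freeze_profiles`` keeps (X, T) at their initial values (useful with
    ``X0``/``T0`` to fit only composition and scale).
    """

    tol: float = 1e-8
    max_iter: int = 1000
    t_min: float = T_MIN
    t_max: float = T_MAX
    free_reference: bool = False
    freeze_profiles: bool = False
    update_precision: bool = True
    X0: np.ndarray | None = None
    T0: np.ndarray | None = None


class _JointState:
    """Mutable state of one joint fit (internal)."""

    def __init__(self, Y0, lab_idx, y1, k, opts: FitOptions):
        m, n0 = Y0.shape
        r = y1.shape[1]
        self.Y0, self.y1, self.lab_idx, self.k, self.opts = (
            Y0, y1, lab_idx, k, opts,
        )
        self.cells_of = [np.flatnonzero(lab_idx == l) for l in range(k)]
        # scale factors from column totals, reference gauge-fixed later
        g0 = np.maximum(Y0.sum(axis=0), 1e-12)
        self.Gref = g0 / np.exp(np.mean(np.log(g0)))
        # initial profiles: per-type scale-normalized mean of the reference
        X = np.zeros((m, k))
        for l in range(k):
            c = self.cells_of[l]
            if c.size:
                X[:, l] = Y0[:, c].sum(axis=1) / self.Gref[c].sum()
        self.X = opts.X0.copy() if opts.X0 is not None else X
        self.T = (
            opts.T0.copy() if opts.T0 is not None else np.ones((m, k))
        )
        self.wb = np.full((k, r), 1.0 / k)
        tot1 = np.maximum(y1.sum(axis=0), 1e-12)
        xsum = (self.X @ self.wb).sum(axis=0)
        self.Gb = tot1 / np.maximum(xsum, 1e-12)
        self.Wref = np.zeros((k, n0))
        self.Wref[lab_idx, np.arange(n0)] = 1.0
        self.Zb = np.zeros((m, k, r))
        self.fallback_genes = 0

    # --- likelihood pieces (pinned quasi-log-likelihood convention) ---

    def ref_loglik(self, T=None, X=None, Gref=None) -> float:
        T = self.T if T is None else T
        X = self.X if X is None else X
        Gref = self.Gref if Gref is None else Gref
        if self.opts.free_reference:
            lam = (
                X[:, :, None]
                * self.Wref[None, :, :]
                * Gref[None, None, :]
            )
            return float(
                np.sum(
                    scaled_poisson_loglik(
                        self.Zref, lam, T[:, :, None]
                    )
                )
            )
        lam = X[:, self.lab_idx] * Gref[None, :]
        return float(
            np.sum(
                scaled_poisson_loglik(self.Y0, lam, T[:, self.lab_idx])
            )
        )

    def bulk_loglik(self, Zb=None, T=None) -> float:
        Zb = self.Zb if Zb is None else Zb
        T = self.T if T is None else T
        lam = (
            self.X[:, :, None]
            * self.wb[None, :, :]
            * self.Gb[None, None, :]
        )
        return float(
            np.sum(scaled_poisson_loglik(Zb, lam, T[:, :, None]))
        )

    def loglik(self) -> float:
        return self.ref_loglik() + self.bulk_loglik()


def _damped_estep(state: _JointState) -> None:
    """Proportional allocation of bulk counts, with a backtracking line
    search along the segment to the new allocation if the full step would
    reduce the bulk-block objective (the objective is concave along the
    segment, and every point on it conserves the observed counts)."""
    m, k, r = state.Zb.shape
    Znew = np.empty_like(state.Zb)
    fallback = 0
    for s in range(r):
        num = state.X * state.wb[:, s][None, :]
        fallback += int(
            np.count_nonzero((num.sum(axis=1) == 0) & (state.y1[:, s] > 0))
        )
        Znew[:, :, s] = allocation_matrix(
            state.y1[:, s], state.X, state.wb[:, s]
        )
    state.fallback_genes = fallback
    if not np.any(state.Zb):  # first iteration: accept outright
        state.Zb = Znew
        return
    f0 = state.bulk_loglik(state.Zb)
    f1 = state.bulk_loglik(Znew)
    if f1 >= f0 - 1e-12 * max(1.0, abs(f0)):
        state.Zb = Znew
        return
    lo, hi = 0.0, 1.0
    Zold = state.Zb
    for _ in range(40):  # ternary search on the concave section
        a = lo + (hi - lo) / 3.0
        b = hi - (hi - lo) / 3.0
        fa = state.bulk_loglik(Zold + a * (Znew - Zold))
        fb = state.bulk_loglik(Zold + b * (Znew - Zold))
        if fa < fb:
            lo = a
        else:
            hi = b
    s_opt = 0.5 * (lo + hi)
    Zcand = Zold + s_opt * (Znew - Zold)
    if state.bulk_loglik(Zcand) > f0:
        state.Zb = Zcand


def _inner_composition(state: _JointState, max_inner: int = 2000) -> None:
    """Drive (allocation, composition, scale) of the bulk block to their
    joint fixed point at the current profiles.

    These three blocks are cheap (m x k work per pass) but converge slowly
    when profiles overlap, so they are iterated to convergence inside each
    outer iteration.  A snapshot guard reverts to a single damped step in
    the rare case the fixed-point pass would lower the bulk objective,
    preserving the monotone trace.
    """
    had_alloc = bool(np.any(state.Zb))
    snap = (state.Zb.copy(), state.wb.copy(), state.Gb.copy())
    f0 = state.bulk_loglik() if had_alloc else -np.inf
    # fast fused E+composition passes: the allocation never needs to be
    # materialized because the composition update only uses its T-weighted
    # column sums
    A = state.T * state.X  # (m, k), fixed during the inner loop
    den = A.sum(axis=0)
    ok = den > 0
    m, k, r = state.Zb.shape
    for s in range(r):
        y = state.y1[:, s]
        w = state.wb[:, s].copy()
        for _ in range(max_inner):
            tot = state.X @ w
            live = tot > 0
            ratio = np.zeros(m)
            ratio[live] = y[live] / tot[live]
            num = w * (A.T @ ratio)
            fb = (~live) & (y > 0)
            if np.any(fb):  # composition-only fallback allocation
                num = num + w * (state.T[fb].T @ y[fb]) / max(w.sum(), 1e-300)
            v = np.zeros(k)
            v[ok] = num[ok] / den[ok]
            tsum = v.sum()
            if tsum <= 0:
                break
            w_new = v / tsum
            w_new /= w_new.sum()
            delta = np.max(np.abs(w_new - w))
            w = w_new
            state.Gb[s] = tsum
            if delta < 1e-12:
                break
        state.wb[:, s] = w
    _estep_bulk(state)
    _update_bulk_composition(state)
    if had_alloc and state.bulk_loglik() < f0 - 1e-9 * max(1.0, abs(f0)):
        state.Zb, state.wb, state.Gb = snap
        _damped_estep(state)
        _update_bulk_composition(state)


def _estep_bulk(state: _JointState) -> None:
    m, k, r = state.Zb.shape
    fallback = 0
    for s in range(r):
        num = state.X * state.wb[:, s][None, :]
        fallback += int(
            np.count_nonzero((num.sum(axis=1) == 0) & (state.y1[:, s] > 0))
        )
        state.Zb[:, :, s] = allocation_matrix(
            state.y1[:, s], state.X, state.wb[:, s]
        )
    state.fallback_genes = fallback


def _update_expression(state: _JointState) -> None:
    if state.opts.freeze_profiles:
        return
    m, k, r = state.Zb.shape
    num = state.Zb.sum(axis=2)
    den = (state.wb * state.Gb[None, :]).sum(axis=1)  # (k,)
    if state.opts.free_reference:
        num = num + state.Zref.sum(axis=2)
        den = den + (state.Wref * state.Gref[None, :]).sum(axis=1)
    else:
        for l in range(k):
            c = state.cells_of[l]
            if c.size:
                num[:, l] += state.Y0[:, c].sum(axis=1)
                den[l] += state.Gref[c].sum()
    X = np.zeros_like(num)
    ok = den > 0
    X[:, ok] = num[:, ok] / den[ok][None, :]
    state.X = X


def _update_bulk_composition(state: _JointState) -> None:
    k, r = state.wb.shape
    den = (state.T * state.X).sum(axis=0)  # (k,)
    for s in range(r):
        num = (state.T * state.Zb[:, :, s]).sum(axis=0)
        v = np.zeros(k)
        ok = den > 0
        v[ok] = num[ok] / den[ok]
        tot = v.sum()
        if tot <= 0:
            logger.warning(
                "bulk replicate %d carries no allocation; keeping uniform "
                "composition", s,
            )
            state.wb[:, s] = 1.0 / k
            continue
        w = v / tot
        state.wb[:, s] = w / w.sum()
        state.Gb[s] = tot


def _update_reference_scales(state: _JointState) -> None:
    if state.opts.free_reference:
        den_l = (state.T * state.X).sum(axis=0)  # per-type, (k,)
        for j in range(state.Gref.size):
            num = (state.T * state.Zref[:, :, j]).sum(axis=0)
            v = np.zeros(state.k)
            ok = den_l > 0
            v[ok] = num[ok] / den_l[ok]
            tot = v.sum()
            if tot > 0:
                w = v / tot
                state.Wref[:, j] = w / w.sum()
                state.Gref[j] = tot
    else:
        for l in range(state.k):
            c = state.cells_of[l]
            if not c.size:
                continue
            den = float((state.T[:, l] * state.X[:, l]).sum())
            if den <= 0:
                continue
            num = state.T[:, l] @ state.Y0[:, c]
            state.Gref[c] = np.maximum(num / den, 1e-12)
    # gauge: geometric mean of reference scales is one; compensate in X
    g = float(np.exp(np.mean(np.log(np.maximum(state.Gref, 1e-300)))))
    state.Gref /= g
    state.Gb /= g
    if not state.opts.freeze_profiles:
        state.X *= g
    else:
        # cannot touch frozen profiles; undo the gauge move instead
        state.Gref *= g
        state.Gb *= g


def _update_precision(state: _JointState) -> float | None:
    """Guarded moment-matching precision update.

    Returns the joint quasi-log-likelihood after the update (assembled from
    the per-entry terms the ascent guard computes anyway), or ``None`` when
    the update is disabled.
    """
    if state.opts.freeze_profiles or not state.opts.update_precision:
        return None
    m, k, r = state.Zb.shape
    num = np.zeros((m, k))
    den = np.zeros((m, k))
    free = state.opts.free_reference
    if free:
        # reference allocations are latent: same conditional-variance
        # treatment as the bulk block
        lam_r = (
            state.X[:, :, None]
            * state.Wref[None, :, :]
            * state.Gref[None, None, :]
        )
        y0 = state.Y0[:, None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            p0 = np.where(y0 > 0, state.Zref / np.maximum(y0, 1e-300), 0.0)
        cv0 = y0 * p0 * (1.0 - p0) / state.T[:, :, None]
        num += lam_r.sum(axis=2)
        den += ((state.Zref - lam_r) ** 2 + cv0).sum(axis=2)
    else:
        # pure labelled units observed directly (zero conditional variance)
        for l in range(k):
            c = state.cells_of[l]
            if not c.size:
                continue
            lam = state.X[:, l][:, None] * state.Gref[c][None, :]
            num[:, l] += lam.sum(axis=1)
            den[:, l] += ((state.Y0[:, c] - lam) ** 2).sum(axis=1)
    # bulk block: allocated counts with a dispersion-scaled multinomial
    # conditional variance around the allocation
    lam_b = (
        state.X[:, :, None] * state.wb[None, :, :] * state.Gb[None, None, :]
    )
    y = state.y1[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(y > 0, state.Zb / np.maximum(y, 1e-300), 0.0)
    cv = y * p * (1.0 - p) / state.T[:, :, None]
    num += lam_b.sum(axis=2)
    den += ((state.Zb - lam_b) ** 2 + cv).sum(axis=2)
    # pooled moment-matched candidate (same rule as m_step_precision, on
    # the pre-accumulated sufficient statistics)
    info = num > 0
    with np.errstate(divide="ignore"):
        est = np.where(den > 0, num / np.maximum(den, 1e-300), np.inf)
    T_new = state.T.copy()
    T_new[info] = np.clip(
        est[info], state.opts.t_min, state.opts.t_max
    )
    # entrywise ascent guard on the traced (unnormalized) objective:
    # accept an entry's new precision only if it does not lower the joint
    # quasi-log-likelihood contribution of that (gene, cell type)
    ll_old = np.zeros((m, k))
    ll_new = np.zeros((m, k))
    if free:
        ll_old += scaled_poisson_loglik(
            state.Zref, lam_r, state.T[:, :, None]
        ).sum(axis=2)
        ll_new += scaled_poisson_loglik(
            state.Zref, lam_r, T_new[:, :, None]
        ).sum(axis=2)
    else:
        for l in range(k):
            c = state.cells_of[l]
            if not c.size:
                continue
            lam = state.X[:, l][:, None] * state.Gref[c][None, :]
            ll_old[:, l] += scaled_poisson_loglik(
                state.Y0[:, c], lam, state.T[:, l][:, None]
            ).sum(axis=1)
            ll_new[:, l] += scaled_poisson_loglik(
                state.Y0[:, c], lam, T_new[:, l][:, None]
            ).sum(axis=1)
    ll_old += scaled_poisson_loglik(
        state.Zb, lam_b, state.T[:, :, None]
    ).sum(axis=2)
    ll_new += scaled_poisson_loglik(
        state.Zb, lam_b, T_new[:, :, None]
    ).sum(axis=2)
    accept = ll_new >= ll_old
    state.T = np.where(accept, T_new, state.T)
    return float(np.sum(np.where(accept, ll_new, ll_old)))


def fit_joint(
    sc: CountMatrix,
    labels: CellLabels,
    bulk_sample: CountMatrix,
    options: FitOptions | None = None,
    sample_id: str = "sample",
) -> DecompositionResult:
    """Fit the joint reference + bulk model for one bulk sample.

    ``bulk_sample`` holds the sample's replicates as columns (typically
    one); replicates share the adapted profiles (X, T) but each gets its
    own composition and scale.  Gene ids of ``sc`` and ``bulk_sample`` must
    already be aligned (see :func:`prism.io.align_labels` and gene
    intersection helpers in :mod:`prism.io`).

    Returns a :class:`DecompositionResult` whose allocations partition the
    observed bulk counts exactly and whose log-likelihood trace is
    non-decreasing.
    """
    opts = options or FitOptions()
    if sc.gene_ids != bulk_sample.gene_ids:
        raise ValidationError(
            "reference and bulk gene ids differ; align them first"
        )
    if set(labels.unit_ids) != set(sc.unit_ids):
        raise ValidationError(
            "labels must cover exactly the reference units; use align_labels"
        )
    order = {u: i for i, u in enumerate(labels.unit_ids)}
    lab = labels.select_units([order[u] for u in sc.unit_ids])
    k = lab.n_types
    if k < 1:
        raise ValidationError("need at least one cell type")
    lab_idx = lab.type_index()

    state = _JointState(
        sc.values, lab_idx, bulk_sample.values, k, opts
    )
    if opts.free_reference:
        # latent reference allocations start at the labelled one-hot split
        m, n0 = sc.values.shape
        state.Zref = np.zeros((m, k, n0))
        state.Zref[:, lab_idx, np.arange(n0)] = sc.values

    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(opts.max_iter):
        n_iter = it + 1
        _inner_composition(state)
        if opts.free_reference:
            _free_reference_estep(state)
        _update_expression(state)
        _update_reference_scales(state)
        ll = _update_precision(state)
        if ll is None:
            ll = state.loglik()
        trace.append(ll)
        if it > 0:
            prev = trace[-2]
            if abs(ll - prev) <= opts.tol * (1.0 + abs(prev)):
                converged = True
                break
    if not converged:
        logger.warning(
            "sample %s: fit did not converge in %d iterations", sample_id,
            opts.max_iter,
        )
    if state.fallback_genes:
        logger.info(
            "sample %s: %d gene/replicate counts allocated by the "
            "composition-only fallback (zero model mean)",
            sample_id, state.fallback_genes,
        )

    alloc = allocate_bulk(state.X, state.wb, bulk_sample)
    return DecompositionResult(
        composition=state.wb.copy(),
        scale=state.Gb.copy(),
        X=state.X.copy(),
        T=state.T.copy(),
        allocations=alloc,
        loglik_trace=np.array(trace),
        converged=converged,
        n_iter=n_iter,
        gene_ids=list(sc.gene_ids),
        type_names=list(lab.type_names),
        replicate_ids=list(bulk_sample.unit_ids),
        sample_id=sample_id,
    )


def _free_reference_estep(state: _JointState) -> None:
    m, k, n0 = state.Zref.shape
    for j in range(n0):
        state.Zref[:, :, j] = allocation_matrix(
            state.Y0[:, j], state.X, state.Wref[:, j]
        )


def allocate_bulk(X, composition, bulk_sample: CountMatrix) -> np.ndarray:
    """Expected cell-type split of bulk counts under fitted parameters.

    Applies the proportional allocation rule gene-by-gene and replicate-by-
    replicate; the cell-type sum reproduces the observed counts exactly.

    Parameters
    ----------
    X : (m, k) fitted mean expression.
    composition : (k, r) fitted compositions, or (k,) for one replicate.
    """
    W = np.asarray(composition, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    m, k = X.shape
    r = bulk_sample.n_units
    out = np.zeros((m, k, r))
    for s in range(r):
        out[:, :, s] = allocation_matrix(
            bulk_sample.values[:, s], X, W[:, s]
        )
    return out


@dataclass
class CohortResult:
    """Per-sample decomposition results plus a record of failed samples."""

    results: list[DecompositionResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    def composition_matrix(self) -> np.ndarray:
        """Stack per-replicate compositions, (k, total replicates)."""
        return np.concatenate([r.composition for r in self.results], axis=1)


def decompose_cohort(
    sc: CountMatrix,
    labels: CellLabels,
    bulk: CountMatrix,
    replicate_map: dict[str, Sequence[str]] | None = None,
    options: FitOptions | None = None,
) -> CohortResult:
    """Decompose every bulk sample of a cohort independently.

    ``replicate_map`` groups bulk columns (by unit id) into samples whose
    replicates share adapted profiles; by default each column is its own
    sample.  Samples are fitted independently, so results do not depend on
    order, and one sample's failure is recorded without aborting the rest.
    """
    if replicate_map is None:
        replicate_map = {u: [u] for u in bulk.unit_ids}
    col = {u: i for i, u in enumerate(bulk.unit_ids)}
    out = CohortResult()
    for sample_id, reps in replicate_map.items():
        missing = [u for u in reps if u not in col]
        if missing:
            out.failures[sample_id] = f"unknown bulk columns {missing}"
            continue
        sub = bulk.select_units([col[u] for u in reps])
        try:
            out.results.append(
                fit_joint(sc, labels, sub, options, sample_id=sample_id)
            )
        except Exception as exc:  # record, keep going
            logger.error("sample %s failed: %s", sample_id, exc)
            out.failures[sample_id] = str(exc)
    if out.failures:
        logger.warning(
            "cohort finished with %d failed sample(s): %s",
            len(out.failures), ", ".join(sorted(out.failures)),
        )
    return out
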