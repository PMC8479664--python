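"""Scaled-Poisson readout model: quasi-likelihood and E/M building blocks.

The readout model assumes latent cell-type-specific counts Z with
``T . Z ~ Poisson(T . X . W . G)`` per gene, cell type and unit, where X is
mean expression, T readout precision (inverse dispersion), W the simplex
composition and G the per-unit scale factor.  The implied readout has mean
``lambda = X W G`` and variance ``lambda / t``: t < 1 is overdispersion,
t > 1 underdispersion, t = 1 exactly Poisson.

Two likelihood conventions appear in this package and are kept deliberately
distinct:

* :func:`scaled_poisson_loglik` -- the unnormalized quasi-log-likelihood
  ``t z log(t lam) - t lam - lgamma(t z + 1)`` (the Poisson log-pmf of
  ``t Z`` evaluated at ``t z`` with the continuous log-gamma extension).
  This is the objective the joint decomposition ascends; only relative
  values at fixed T matter to its coordinate updates.
* :func:`scaled_poisson_logpdf` -- the same plus ``log t``, i.e. the
  (approximate) log-*density* of Z itself, accounting for the 1/t lattice
  spacing.  Model comparisons across different precisions (trimmed-gene
  ranking, clustering likelihoods and BIC) must use this normalized form;
  under it, moment matching of T is approximately the maximum-likelihood
  update, which the unnormalized form does not admit.

All functions broadcast over numpy arrays and treat the degenerate point
mass ``lam = 0`` as: 0 at z = 0, -inf at z > 0.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .datamodel import (
    CountMatrix,
    ModelParams,
    ValidationError,
    T_MIN,
    T_MAX,
)

__all__ = [
    "scaled_poisson_loglik",
    "scaled_poisson_logpdf",
    "expected_allocation",
    "allocation_matrix",
    "joint_loglik",
    "m_step_expression",
    "m_step_composition",
    "m_step_precision",
]


def scaled_poisson_loglik(z, mean, precision):
    """Unnormalized scaled-Poisson quasi-log-likelihood, elementwise.

    ``ll(z; lam, t) = t z log(t lam) - t lam - lgamma(t z + 1)``.

    At t = 1 and integer z this is exactly the Poisson log-pmf.  Arguments
    broadcast; scalars in, scalar out.

    Raises
    ------
    ValidationError
        If any ``z`` or ``mean`` is negative, or any precision is outside
        the global bounds ``[T_MIN, T_MAX]``.
    """
    z = np.asarray(z, dtype=float)
    lam = np.asarray(mean, dtype=float)
    t = np.asarray(precision, dtype=float)
    if np.any(z < 0):
        raise ValidationError("negative count z")
    if np.any(lam < 0):
        raise ValidationError("negative mean")
    if np.any(t < T_MIN - 1e-12) or np.any(t > T_MAX + 1e-12):
        raise ValidationError(f"precision outside [{T_MIN}, {T_MAX}]")
    z, lam, t = np.broadcast_arrays(z, lam, t)
    out = np.empty(z.shape, dtype=float)
    pos = lam > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tl = t[pos] * lam[pos]
        tz = t[pos] * z[pos]
        # 0 * log(.) = 0 at z == 0
        out[pos] = (
            np.where(tz > 0, tz * np.log(tl), 0.0)
            - tl
            - gammaln(tz + 1.0)
        )
    zero = ~pos
    out[zero] = np.where(z[zero] > 0, -np.inf, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def scaled_poisson_logpdf(z, mean, precision):
    """Normalized scaled-Poisson log-density: ``log t`` + quasi-log-lik.

    The quasi-log-likelihood is the Poisson log-pmf on the 1/t lattice;
    multiplying by the lattice density t converts it to an (approximate)
    density for Z, making values comparable across different precisions.
    The ``lam = 0, z = 0`` point mass contributes 0 (no Jacobian).
    """
    z = np.asarray(z, dtype=float)
    lam = np.asarray(mean, dtype=float)
    t = np.asarray(precision, dtype=float)
    base = scaled_poisson_loglik(z, lam, t)
    z, lam, t = np.broadcast_arrays(z, lam, t)
    jac = np.where(lam > 0, np.log(t), 0.0)
    out = base + jac
    if np.ndim(out) == 0:
        return float(out)
    return out


def expected_allocation(y_i, x_row, w):
    """Expected split of one observed count over cell types.

    Returns ``y_i * (x_row * w) / sum(x_row * w)``; the components sum to
    ``y_i`` exactly.  If the denominator is zero (the current profiles
    cannot explain the gene) and ``y_i > 0``, the count is allocated
    proportionally to ``w`` alone so that conservation stays exact; at
    ``y_i = 0`` the all-zero vector is returned.
    """
    x_row = np.asarray(x_row, dtype=float)
    w = np.asarray(w, dtype=float)
    if y_i < 0:
        raise ValidationError("negative observed count")
    num = x_row * w
    tot = num.sum()
    if y_i == 0:
        return np.zeros_like(num)
    if tot <= 0:
        wtot = w.sum()
        if wtot <= 0:
            # fully degenerate: spread uniformly
            return np.full(w.shape, y_i / w.size)
        return y_i * (w / wtot)
    p = num / tot
    return y_i * (p / p.sum())


def allocation_matrix(y, X, w):
    """Vectorized :func:`expected_allocation` over all genes of one unit.

    Parameters
    ----------
    y : (m,) observed counts for one unit.
    X : (m, k) mean expression.
    w : (k,) composition (need not be normalized; only direction matters).

    Returns
    -------
    (m, k) array whose rows sum to ``y`` exactly.
    """
    y = np.asarray(y, dtype=float)
    num = X * w[None, :]
    tot = num.sum(axis=1)
    out = np.zeros_like(num)
    ok = tot > 0
    p = num[ok] / tot[ok, None]
    out[ok] = y[ok, None] * (p / p.sum(axis=1, keepdims=True))
    bad = (~ok) & (y > 0)
    if np.any(bad):
        wtot = w.sum()
        fallback = w / wtot if wtot > 0 else np.full(w.shape, 1.0 / w.size)
        out[bad] = y[bad, None] * fallback[None, :]
    return out


def _block_loglik(Z, X, T, W, G):
    """Sum of quasi-log-likelihood terms for one data block.

    Z : (m, k, n) allocated latent counts; mean is X[i,l] W[l,j] G[j].
    """
    lam = X[:, :, None] * W[None, :, :] * G[None, None, :]
    return float(np.sum(scaled_poisson_loglik(Z, lam, T[:, :, None])))


def joint_loglik(sc, bulk, params, sc_allocation, bulk_allocation):
    """Complete-data quasi-log-likelihood of the joint reference+bulk model.

    The single-cell block uses the leading ``n0`` columns of ``params.W``
    and ``params.G``; the bulk block the remaining ``r`` columns.  Both
    blocks share the expression profiles (X, T); this is what lets the bulk
    adapt the profiles while the reference anchors them.

    Parameters
    ----------
    sc, bulk : CountMatrix
        Observed single-cell and bulk counts on a shared gene index.
    params : ModelParams
        With W of shape (k, n0 + r) and G of length n0 + r.
    sc_allocation : (m, k, n0) latent allocation of the reference counts.
    bulk_allocation : (m, k, r) latent allocation of the bulk counts.
    """
    if not isinstance(params, ModelParams):
        raise ValidationError("params must be ModelParams")
    m = params.n_genes
    if sc.n_genes != m or bulk.n_genes != m:
        raise ValidationError("gene dimension mismatch")
    n0, r = sc.n_units, bulk.n_units
    if params.W.shape[1] != n0 + r:
        raise ValidationError("W must cover reference and bulk units")
    if sc_allocation.shape != (m, params.n_types, n0):
        raise ValidationError("sc_allocation has wrong shape")
    if bulk_allocation.shape != (m, params.n_types, r):
        raise ValidationError("bulk_allocation has wrong shape")
    ll = _block_loglik(
        sc_allocation, params.X, params.T, params.W[:, :n0], params.G[:n0]
    )
    ll += _block_loglik(
        bulk_allocation, params.X, params.T, params.W[:, n0:], params.G[n0:]
    )
    return ll


def m_step_expression(allocations, W, G):
    """Closed-form update of mean expression X given allocations.

    ``X[i,l] = sum_j Z[i,l,j] / sum_j W[l,j] G[j]`` pooled over all units
    (reference and bulk alike).  The precision T cancels in the stationarity
    condition, so this is the exact quasi-likelihood maximizer in X for any
    fixed T.  Entries with zero total allocation and zero denominator are
    set to 0.

    Parameters
    ----------
    allocations : (m, k, n) latent allocations over all units.
    W : (k, n) compositions.
    G : (n,) scale factors.
    """
    num = allocations.sum(axis=2)
    den = (W * G[None, :]).sum(axis=1)  # (k,)
    X = np.zeros_like(num)
    ok = den > 0
    X[:, ok] = num[:, ok] / den[ok][None, :]
    return X


def m_step_composition(allocation, X, T, G_j):
    """Composition update for one unit, with the scale absorbing the total.

    Maximizes the quasi-likelihood jointly in ``v[l] = w[l] * G_j`` (the
    problem is separable and concave in v), then splits the maximizer into
    a simplex composition and an updated scale:

    ``v[l] = sum_i T[i,l] Z[i,l] / sum_i T[i,l] X[i,l]``;
    ``w = v / sum(v)``; ``G_new = sum(v)``.

    Returns
    -------
    (w, G_new, degenerate) : the simplex vector, the updated scale and a
    flag set when the allocation carried no information (uniform w
    returned, scale kept).
    """
    num = (T * allocation).sum(axis=0)  # (k,)
    den = (T * X).sum(axis=0)  # (k,)
    v = np.zeros_like(num)
    ok = den > 0
    v[ok] = num[ok] / den[ok]
    tot = v.sum()
    k = v.size
    if tot <= 0:
        return np.full(k, 1.0 / k), float(G_j), True
    w = v / tot
    w = w / w.sum()  # exact simplex within float rounding
    return w, float(tot), False


def m_step_precision(
    allocations,
    means,
    current_t,
    cond_var=None,
    t_min: float = T_MIN,
    t_max: float = T_MAX,
):
    """Moment-matching update of the readout precision T.

    The scaled-Poisson variance is ``lam / t``, so T is estimated per
    (gene, cell type) as the ratio of summed means to the summed conditional
    second moment of the residuals,

    ``T[i,l] = clamp( sum_j lam[i,l,j] /
                      sum_j ( (Z[i,l,j] - lam[i,l,j])^2 + cond_var[i,l,j] ),
                      t_min, t_max )``,

    where ``cond_var`` carries the conditional variance of the latent count
    around its allocated expectation (zero for directly observed pure
    units).  Entries with no information (zero summed mean) keep their
    current value; zero empirical variance clamps to ``t_max``.

    Parameters
    ----------
    allocations, means : (m, k, n) arrays (or (m, k) for a single unit).
    current_t : (m, k) current precision, kept where no update is possible.
    cond_var : optional (m, k, n) conditional variances; default zero.
    """
    Z = np.asarray(allocations, dtype=float)
    lam = np.asarray(means, dtype=float)
    if Z.ndim == 2:
        Z = Z[:, :, None]
        lam = lam[:, :, None]
    sq = (Z - lam) ** 2
    if cond_var is not None:
        cv = np.asarray(cond_var, dtype=float)
        if cv.ndim == 2:
            cv = cv[:, :, None]
        sq = sq + cv
    num = lam.sum(axis=2)
    den = sq.sum(axis=2)
    T = np.array(np.broadcast_to(current_t, num.shape), dtype=float)
    info = num > 0
    with np.errstate(divide="ignore"):
        est = np.where(den > 0, num / np.maximum(den, 1e-300), np.inf)
    T[info] = np.clip(est[info], t_min, t_max)
    return T
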