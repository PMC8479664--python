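"""Generative simulator for the scaled-Poisson mixture model.

Runs the readout model forward to produce labelled single-cell references,
bulk mixtures and the ground truth needed by every recovery test: true
profiles, compositions, scale factors and latent cell-type-specific counts.

Sampling the scaled-Poisson readout (``t Z ~ Poisson(t lam)`` on the 1/t
lattice) is done by moment matching the first two moments (mean ``lam``,
variance ``lam / t``):

* t = 1: exact Poisson.
* t < 1 (overdispersed): gamma-Poisson mixture with gamma shape
  ``lam t / (1 - t)`` and scale ``(1 - t) / t``, whose compound variance is
  exactly ``lam / t``.
* t > 1 (underdispersed): ``round(Poisson(t lam) / t)``, approximately
  moment matched (exactly in the mean up to rounding).

Default sizes emulate a desk-scale tumor deconvolution study: 500 genes,
3 cell types (cancer, fibroblast, immune), 100 reference cells per type at
~2000 counts per cell, bulk depth 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .datamodel import CellLabels, CountMatrix, ModelParams, ValidationError

__all__ = [
    "SimulationTruth",
    "CohortBundle",
    "simulate_reference",
    "simulate_bulk",
    "simulate_cohort",
    "sample_scaled_poisson",
    "SCENARIOS",
]

_DEFAULT_TYPES = ["EOC", "Fibroblast", "Immune"]


@dataclass
class SimulationTruth:
    """Ground truth emitted by the generator.

    ``params`` holds the true (X, T, W, G); ``latent`` the true per-unit
    cell-type-specific counts, shape (m, k, n_units); ``design`` records the
    generator settings including the seed.  For bulk simulations with
    per-sample profile perturbation, ``perturbed_X`` (m, k, n) stores the
    per-sample true profiles and ``perturbed_genes`` the gene indices
    touched per sample.
    """

    params: ModelParams
    latent: np.ndarray
    design: dict[str, Any] = field(default_factory=dict)
    perturbed_X: np.ndarray | None = None
    perturbed_genes: list[np.ndarray] | None = None


@dataclass
class CohortBundle:
    """Reference + bulk + truth produced by a named scenario."""

    reference: CountMatrix
    labels: CellLabels
    reference_truth: SimulationTruth
    bulk: CountMatrix
    bulk_truth: SimulationTruth
    design: dict[str, Any] = field(default_factory=dict)


def sample_scaled_poisson(rng: np.random.Generator, lam, t: float):
    """Draw counts with mean ``lam`` and variance ``lam / t`` (see module)."""
    lam = np.asarray(lam, dtype=float)
    if t <= 0:
        raise ValidationError("dispersion parameter t must be positive")
    if np.any(lam < 0):
        raise ValidationError("negative mean")
    if t == 1.0:
        return rng.poisson(lam).astype(float)
    if t < 1.0:
        shape = lam * t / (1.0 - t)
        scale = (1.0 - t) / t
        mix = np.zeros_like(lam)
        pos = lam > 0
        mix[pos] = rng.gamma(shape[pos], scale)
        return rng.poisson(mix).astype(float)
    return np.round(rng.poisson(t * lam) / t)


def _lognormal_profiles(
    rng: np.random.Generator,
    m: int,
    k: int,
    base_sdlog: float,
    type_sdlog: float,
) -> np.ndarray:
    """Relative expression profiles: shared log-normal base with per-type
    log-normal fold deviations; columns normalized to sum to one."""
    base = rng.lognormal(0.0, base_sdlog, size=m)
    folds = rng.lognormal(0.0, type_sdlog, size=(m, k))
    X = base[:, None] * folds
    return X / X.sum(axis=0, keepdims=True)


def _marker_profiles(
    m: int, k: int, n_markers: int, marker_expr: float, background_expr: float
) -> np.ndarray:
    """Disjoint marker blocks: genes [l*n_markers, (l+1)*n_markers) express
    ``marker_expr`` in type l; everything else ``background_expr``.  Values
    are absolute per-cell means (columns are not normalized)."""
    if n_markers * k > m:
        raise ValidationError("marker blocks exceed gene count")
    X = np.full((m, k), background_expr, dtype=float)
    for l in range(k):
        X[l * n_markers : (l + 1) * n_markers, l] = marker_expr
    return X


def simulate_reference(
    m: int = 500,
    k: int = 3,
    cells_per_type: int = 100,
    depth_mean: float = 2000.0,
    dispersion_t: float = 1.0,
    profile_spec: dict[str, Any] | None = None,
    seed: int = 0,
    depth_sdlog: float = 0.25,
    type_names: list[str] | None = None,
):
    """Simulate a labelled single-cell reference.

    Returns ``(counts, labels, truth)``.  Profiles are either correlated
    log-normal draws (``{"kind": "lognormal", "base_sdlog", "type_sdlog"}``,
    the default) or disjoint marker blocks (``{"kind": "markers",
    "n_markers", "marker_expr", "background_expr"}``).  Per-cell scale
    factors are log-normal with mean ``depth_mean`` for log-normal profiles;
    for marker profiles the absolute means ARE the profile and the scale is
    log-normal with mean one.
    """
    if min(m, k, cells_per_type) < 1:
        raise ValidationError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    spec = dict(profile_spec or {"kind": "lognormal"})
    kind = spec.get("kind", "lognormal")
    if kind == "lognormal":
        X = _lognormal_profiles(
            rng,
            m,
            k,
            float(spec.get("base_sdlog", 1.0)),
            float(spec.get("type_sdlog", 0.7)),
        )
        g_mean = depth_mean
    elif kind == "markers":
        X = _marker_profiles(
            m,
            k,
            int(spec.get("n_markers", 50)),
            float(spec.get("marker_expr", 20.0)),
            float(spec.get("background_expr", 0.1)),
        )
        g_mean = 1.0
    else:
        raise ValidationError(f"unknown profile spec kind {kind!r}")

    n = k * cells_per_type
    type_idx = np.repeat(np.arange(k), cells_per_type)
    G = rng.lognormal(
        np.log(g_mean) - 0.5 * depth_sdlog**2, depth_sdlog, size=n
    )
    lam = X[:, type_idx] * G[None, :]
    counts = sample_scaled_poisson(rng, lam, dispersion_t)

    names = list(type_names or _DEFAULT_TYPES[:k])
    while len(names) < k:
        names.append(f"C{len(names) + 1}")
    names = names[:k]
    unit_ids = [f"cell_{j:04d}" for j in range(n)]
    gene_ids = [f"gene_{i:04d}" for i in range(m)]
    cm = CountMatrix(counts, gene_ids, unit_ids, kind="single_cell")
    labels = CellLabels(unit_ids, [names[t] for t in type_idx], names)

    W = np.zeros((k, n))
    W[type_idx, np.arange(n)] = 1.0
    latent = np.zeros((m, k, n))
    latent[:, type_idx, np.arange(n)] = counts
    truth = SimulationTruth(
        params=ModelParams(
            X, np.full((m, k), np.clip(dispersion_t, 1e-3, 1e3)), W, G
        ),
        latent=latent,
        design=dict(
            m=m,
            k=k,
            cells_per_type=cells_per_type,
            depth_mean=depth_mean,
            depth_sdlog=depth_sdlog,
            dispersion_t=dispersion_t,
            profile_spec=spec,
            seed=seed,
        ),
    )
    return cm, labels, truth


def simulate_bulk(
    truth_profiles: np.ndarray,
    compositions: np.ndarray,
    depth: float = 1e6,
    dispersion_t: float = 1.0,
    perturbation_spec: dict[str, Any] | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    type_names: list[str] | None = None,
):
    """Simulate bulk mixtures from true profiles and compositions.

    Parameters
    ----------
    truth_profiles : (m, k) relative expression (columns sum to one).
    compositions : (k, n) simplex columns, one per bulk sample.
    perturbation_spec : optional per-sample profile perturbation emulating
        sample-specific expression states: ``{"fraction": 0.1, "sdlog": 0.5,
        "types": [0]}`` multiplies the stated fraction of genes of the
        stated profile columns by log-normal fold noise before mixing (each
        sample draws its own genes and folds); the perturbed per-sample
        profiles are recorded in the truth as the adaptation target.

    Returns ``(counts, truth)``.
    """
    X = np.asarray(truth_profiles, dtype=float)
    Wb = np.asarray(compositions, dtype=float)
    m, k = X.shape
    if Wb.ndim != 2 or Wb.shape[0] != k:
        raise ValidationError("compositions must be (k, n)")
    if np.any(Wb < 0) or np.any(np.abs(Wb.sum(axis=0) - 1.0) > 1e-9):
        raise ValidationError("composition columns must be on the simplex")
    n = Wb.shape[1]
    rng = np.random.default_rng(seed)

    perX = np.repeat(X[:, :, None], n, axis=2)
    pert_genes: list[np.ndarray] = []
    if perturbation_spec:
        frac = float(perturbation_spec.get("fraction", 0.1))
        sdlog = float(perturbation_spec.get("sdlog", 0.5))
        types = list(perturbation_spec.get("types", [0]))
        n_pert = int(round(frac * m))
        for s in range(n):
            genes = rng.choice(m, size=n_pert, replace=False)
            genes.sort()
            for l in types:
                folds = rng.lognormal(0.0, sdlog, size=n_pert)
                perX[genes, l, s] *= folds
            # renormalize perturbed columns so compositions keep their
            # count-fraction meaning
            for l in types:
                perX[:, l, s] /= perX[:, l, s].sum()
            pert_genes.append(genes)
    else:
        pert_genes = [np.array([], dtype=int) for _ in range(n)]

    latent = np.zeros((m, k, n))
    for s in range(n):
        lam = perX[:, :, s] * Wb[:, s][None, :] * depth
        latent[:, :, s] = sample_scaled_poisson(rng, lam, dispersion_t)
    counts = latent.sum(axis=1)

    gene_ids = list(gene_ids or (f"gene_{i:04d}" for i in range(m)))
    unit_ids = [f"bulk_{s:02d}" for s in range(n)]
    cm = CountMatrix(counts, gene_ids, unit_ids, kind="bulk")
    truth = SimulationTruth(
        params=ModelParams(
            X * depth,
            np.full((m, k), np.clip(dispersion_t, 1e-3, 1e3)),
            Wb,
            np.ones(n),
        ),
        latent=latent,
        design=dict(
            depth=depth,
            dispersion_t=dispersion_t,
            perturbation_spec=perturbation_spec,
            seed=seed,
        ),
        perturbed_X=perX,
        perturbed_genes=pert_genes,
    )
    return cm, truth


def _dirichlet_compositions(
    rng: np.random.Generator, alpha: np.ndarray, n: int
) -> np.ndarray:
    return rng.dirichlet(alpha, size=n).T


def simulate_cohort(scenario: str, seed: int = 0) -> CohortBundle:
    """Produce a named preset cohort of reference + bulk + truth.

    Presets (see :data:`SCENARIOS`): ``baseline`` (3 samples, spread
    compositions), ``shifted-composition`` (treatment-naive-like ~70% vs
    post-chemotherapy-like ~40% cancer fraction), ``perturbed-profiles``
    (one sample whose cancer profile carries log-fold noise, sd 0.5, on 10%
    of genes), ``pure-samples`` (one-hot compositions), ``two-type-markers``
    (two types with disjoint marker blocks, for clustering) and
    ``one-type`` (a single homogeneous population).
    """
    if scenario not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; available: "
            + ", ".join(sorted(SCENARIOS))
        )
    return SCENARIOS[scenario](int(seed))


def _split_seeds(seed: int, n: int = 2) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _baseline(seed: int, *, n_samples=3, alpha=(2.0, 1.2, 0.8),
              perturbation=None, compositions=None) -> CohortBundle:
    s_ref, s_bulk, s_w = _split_seeds(seed, 3)
    ref, labels, ref_truth = simulate_reference(
        m=500, k=3, cells_per_type=100, depth_mean=2000.0, seed=s_ref
    )
    if compositions is None:
        rng = np.random.default_rng(s_w)
        compositions = _dirichlet_compositions(
            rng, np.asarray(alpha, dtype=float), n_samples
        )
    bulk, bulk_truth = simulate_bulk(
        ref_truth.params.X,
        compositions,
        depth=1e6,
        perturbation_spec=perturbation,
        seed=s_bulk,
        gene_ids=ref.gene_ids,
    )
    return CohortBundle(
        ref, labels, ref_truth, bulk, bulk_truth,
        design=dict(scenario="baseline", seed=seed),
    )


def _shifted(seed: int) -> CohortBundle:
    # two treatment-naive-like samples (~70% cancer) and two
    # post-chemotherapy-like samples (~40% cancer)
    s_w = _split_seeds(seed, 3)[2]
    rng = np.random.default_rng(s_w)
    primary = _dirichlet_compositions(rng, np.array([14.0, 4.0, 2.0]), 2)
    interval = _dirichlet_compositions(rng, np.array([8.0, 8.0, 4.0]), 2)
    comps = np.concatenate([primary, interval], axis=1)
    b = _baseline(seed, compositions=comps)
    b.design["scenario"] = "shifted-composition"
    return b


def _perturbed(seed: int) -> CohortBundle:
    comps = np.array([[0.6], [0.3], [0.1]])
    b = _baseline(
        seed,
        compositions=comps,
        perturbation=dict(fraction=0.1, sdlog=0.5, types=[0]),
    )
    b.design["scenario"] = "perturbed-profiles"
    return b


def _pure(seed: int) -> CohortBundle:
    b = _baseline(seed, compositions=np.eye(3))
    b.design["scenario"] = "pure-samples"
    return b


def _two_type_markers(seed: int) -> CohortBundle:
    s_ref, s_bulk = _split_seeds(seed, 2)
    ref, labels, ref_truth = simulate_reference(
        m=200,
        k=2,
        cells_per_type=50,
        dispersion_t=1.0,
        profile_spec=dict(
            kind="markers", n_markers=50, marker_expr=20.0,
            background_expr=0.1,
        ),
        seed=s_ref,
        depth_sdlog=0.25,
        type_names=["TypeA", "TypeB"],
    )
    Xrel = ref_truth.params.X / ref_truth.params.X.sum(axis=0, keepdims=True)
    bulk, bulk_truth = simulate_bulk(
        Xrel,
        np.array([[0.5], [0.5]]),
        depth=1e5,
        seed=s_bulk,
        gene_ids=ref.gene_ids,
    )
    return CohortBundle(
        ref, labels, ref_truth, bulk, bulk_truth,
        design=dict(scenario="two-type-markers", seed=seed),
    )


def _one_type(seed: int) -> CohortBundle:
    s_ref, s_bulk = _split_seeds(seed, 2)
    ref, labels, ref_truth = simulate_reference(
        m=200, k=1, cells_per_type=100, depth_mean=2000.0, seed=s_ref,
        type_names=["TypeA"],
    )
    bulk, bulk_truth = simulate_bulk(
        ref_truth.params.X,
        np.array([[1.0]]),
        depth=1e5,
        seed=s_bulk,
        gene_ids=ref.gene_ids,
    )
    return CohortBundle(
        ref, labels, ref_truth, bulk, bulk_truth,
        design=dict(scenario="one-type", seed=seed),
    )


SCENARIOS = {
    "baseline": _baseline,
    "shifted-composition": _shifted,
    "perturbed-profiles": _perturbed,
    "pure-samples": _pure,
    "two-type-markers": _two_type_markers,
    "one-type": _one_type,
}
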