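"""Core domain types shared by all PRISM modules.

The central objects are count matrices (genes x units, where a unit is either
a bulk replicate or a single cell), cell-type label tables for the reference,
and the identifiable parameterization of the scaled-Poisson readout model:
mean expression ``X`` (genes x cell types), readout precision ``T`` (inverse
dispersion, genes x cell types), relative composition ``W`` (cell types x
units, simplex columns) and per-unit scale factors ``G``.

Counts are stored as non-negative *reals*, not integers: bulk quantification
pipelines commonly emit real-valued "effective counts", and all likelihood
code uses the continuous (log-gamma) extension of the Poisson log-pmf.
Validation happens at construction; downstream code may assume the
invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PrismError",
    "ValidationError",
    "FormatError",
    "CountMatrix",
    "CellLabels",
    "ModelParams",
    "DecompositionResult",
    "T_MIN",
    "T_MAX",
]

#: Default bounds for the readout precision T.  They prevent degenerate
#: infinite-precision sinks on genes with near-zero conditional variance.
T_MIN = 1e-3
T_MAX = 1e3


class PrismError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PrismError, ValueError):
    """Input data violates a model or container invariant."""


class FormatError(PrismError, ValueError):
    """A file does not conform to its declared format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} {dup!r}")


@dataclass
class CountMatrix:
    """Non-negative real count matrix, genes (rows) x units (columns).

    Parameters
    ----------
    values
        ``(m, n)`` array of non-negative, finite reals.
    gene_ids
        ``m`` unique gene identifiers.
    unit_ids
        ``n`` unique unit identifiers (sample, replicate or cell barcodes).
    kind
        ``"bulk"`` or ``"single_cell"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    unit_ids: list[str]
    kind: str = "bulk"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be two-dimensional")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.unit_ids = [str(u) for u in self.unit_ids]
        m, n = self.values.shape
        if m == 0:
            raise ValidationError("no genes")
        if n == 0:
            raise ValidationError("no units")
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} rows"
            )
        if len(self.unit_ids) != n:
            raise ValidationError(
                f"{len(self.unit_ids)} unit ids for {n} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("counts contain NaN or infinite entries")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"unit {self.unit_ids[j]!r}"
            )
        if self.kind not in ("bulk", "single_cell"):
            raise ValidationError(f"unknown count matrix kind {self.kind!r}")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.unit_ids, "unit id")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def select_units(self, index: Sequence[int]) -> "CountMatrix":
        """Return a copy restricted to the units at ``index`` (in order)."""
        index = list(index)
        return CountMatrix(
            self.values[:, index].copy(),
            list(self.gene_ids),
            [self.unit_ids[i] for i in index],
            kind=self.kind,
        )

    def select_genes(self, index: Sequence[int]) -> "CountMatrix":
        """Return a copy restricted to the genes at ``index`` (in order)."""
        index = list(index)
        return CountMatrix(
            self.values[index, :].copy(),
            [self.gene_ids[i] for i in index],
            list(self.unit_ids),
            kind=self.kind,
        )


@dataclass
class CellLabels:
    """Cell-type assignment for reference units.

    ``type_names`` is ordered by first appearance and defines the cell-type
    index used by every downstream matrix (columns of X/T, rows of W).
    """

    unit_ids: list[str]
    labels: list[str]
    type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.unit_ids) != len(self.labels):
            raise ValidationError("unit_ids and labels differ in length")
        if not self.unit_ids:
            raise ValidationError("no labelled units")
        _check_unique(self.unit_ids, "unit id")
        if not self.type_names:
            seen: list[str] = []
            for l in self.labels:
                if l not in seen:
                    seen.append(l)
            self.type_names = seen
        else:
            self.type_names = [str(t) for t in self.type_names]
            _check_unique(self.type_names, "type name")
            missing = set(self.labels) - set(self.type_names)
            if missing:
                raise ValidationError(
                    f"labels {sorted(missing)} missing from type_names"
                )

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def type_index(self) -> np.ndarray:
        """Integer type index per unit, aligned with ``type_names``."""
        lookup = {t: i for i, t in enumerate(self.type_names)}
        return np.array([lookup[l] for l in self.labels], dtype=int)

    def onehot(self) -> np.ndarray:
        """Binary composition matrix W, (n_types, n_units)."""
        w = np.zeros((self.n_types, len(self.unit_ids)))
        w[self.type_index(), np.arange(len(self.unit_ids))] = 1.0
        return w

    def select_units(self, index: Sequence[int]) -> "CellLabels":
        index = list(index)
        return CellLabels(
            [self.unit_ids[i] for i in index],
            [self.labels[i] for i in index],
            list(self.type_names),
        )


@dataclass
class ModelParams:
    """Identifiable parameterization of the scaled-Poisson readout model.

    The physical constants behind the readout (cell count, sampling
    efficiency, per-gene expression mean and variability) are not separately
    identifiable; the model is parameterized by their identifiable
    combinations: mean expression ``X`` (m x k), readout precision ``T``
    (m x k, bounded to [t_min, t_max]), relative composition ``W`` (k x n,
    simplex columns) and scale factors ``G`` (n,).  The remaining joint scale
    ambiguity (X -> cX, G -> G/c) is resolved by fitting code through a gauge
    convention (geometric mean of the reference scale factors equals one).
    """

    X: np.ndarray
    T: np.ndarray
    W: np.ndarray
    G: np.ndarray
    t_min: float = T_MIN
    t_max: float = T_MAX

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.X.ndim != 2 or self.T.shape != self.X.shape:
            raise ValidationError("X and T must be matching m x k matrices")
        m, k = self.X.shape
        if self.W.ndim != 2 or self.W.shape[0] != k:
            raise ValidationError("W must be k x n")
        n = self.W.shape[1]
        if self.G.shape != (n,):
            raise ValidationError("G must have one entry per unit")
        if np.any(self.X < 0) or not np.all(np.isfinite(self.X)):
            raise ValidationError("X must be non-negative and finite")
        if np.any(self.T < self.t_min - 1e-12) or np.any(
            self.T > self.t_max + 1e-12
        ):
            raise ValidationError(
                f"T outside [{self.t_min}, {self.t_max}]"
            )
        if np.any(self.W < 0):
            raise ValidationError("W must be non-negative")
        colsum = self.W.sum(axis=0)
        if np.any(np.abs(colsum - 1.0) > 1e-9):
            raise ValidationError("columns of W must sum to 1 (within 1e-9)")
        if np.any(self.G <= 0) or not np.all(np.isfinite(self.G)):
            raise ValidationError("G must be positive and finite")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_types(self) -> int:
        return self.X.shape[1]


@dataclass
class DecompositionResult:
    """Per-bulk-sample output of the joint decomposition.

    ``allocations`` is the (m, k, r) expected split of each observed bulk
    count over cell types; its cell-type sum reproduces the bulk counts
    exactly (conservation).  ``loglik_trace`` is the joint quasi-log-
    likelihood after each block-coordinate iteration and is non-decreasing
    (up to 1e-8 numerical slack).
    """

    composition: np.ndarray  # (k, r) simplex columns
    scale: np.ndarray  # (r,) bulk scale factors
    X: np.ndarray  # (m, k) adapted mean expression
    T: np.ndarray  # (m, k) adapted readout precision
    allocations: np.ndarray  # (m, k, r)
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    gene_ids: list[str]
    type_names: list[str]
    replicate_ids: list[str]
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.allocations = np.asarray(self.allocations, dtype=float)
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)
        k, r = self.composition.shape
        m = self.X.shape[0]
        if self.allocations.shape != (m, k, r):
            raise ValidationError("allocations must be (genes, types, reps)")
        if np.any(np.abs(self.composition.sum(axis=0) - 1.0) > 1e-9):
            raise ValidationError("composition columns must sum to 1")

    @property
    def bulk_counts(self) -> np.ndarray:
        """Reconstructed bulk counts, (m, r): cell-type sum of allocations."""
        return self.allocations.sum(axis=1)
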