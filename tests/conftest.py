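import numpy as np
import pytest

from prism import CountMatrix, CellLabels, fit_joint, simulate_cohort


def make_counts(values, kind="bulk", prefix="u"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return CountMatrix(
        values,
        [f"g{i}" for i in range(m)],
        [f"{prefix}{j}" for j in range(n)],
        kind=kind,
    )


def make_labels(counts, labels):
    return CellLabels(list(counts.unit_ids), list(labels))


@pytest.fixture(scope="session")
def baseline_cohort():
    """One simulated reference + bulk cohort shared by read-only tests."""
    return simulate_cohort("baseline", seed=11)


@pytest.fixture(scope="session")
def baseline_fit(baseline_cohort):
    """A converged decomposition of the first baseline bulk sample."""
    b = baseline_cohort
    return fit_joint(b.reference, b.labels, b.bulk.select_units([0]))
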