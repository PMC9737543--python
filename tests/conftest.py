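import numpy as np
import pytest

from vagkit import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def fast_params():
    """Short recordings for tests where the 20-s default would be wasteful."""
    return SimulationParams(duration=4.0, n_cycles=2)


@pytest.fixture(scope="session")
def small_cohort():
    """15+15 subjects, 2 sessions, default (well-separated) signal parameters."""
    manifest, recordings = simulate_cohort(15, 15, 2, SimulationParams(), seed=42)
    return manifest, recordings


def brute_force_anova(x: np.ndarray) -> tuple[float, float, float]:
    """Independent two-way ANOVA mean squares via explicit loops.

    Deliberately naive (no vectorisation, no shared code with the package)
    so it can serve as an oracle for the implementation.
    """
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def brute_force_icc_a1(x: np.ndarray) -> float:
    """ICC(A,1) from the brute-force mean squares."""
    n, k = x.shape
    msr, msc, mse = brute_force_anova(x)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
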