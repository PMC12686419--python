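import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_cohort():
    """The packaged 200-case worked-example cohort (cube, metadata)."""
    from vbdg import reference_cohort

    return reference_cohort()


@pytest.fixture()
def small_cube():
    """4 cases x 3 conditions x {1,3,5}, hand-constructed and monotone."""
    from vbdg import CorrectnessCube

    values = np.array(
        [
            [[1, 1, 1], [0, 1, 1], [0, 0, 1]],
            [[0, 0, 1], [1, 1, 1], [0, 0, 0]],
            [[1, 1, 1], [0, 0, 0], [1, 1, 1]],
            [[0, 1, 1], [0, 0, 1], [0, 1, 1]],
        ],
        dtype=np.uint8,
    )
    return CorrectnessCube(values, ("c1", "c2", "c3", "c4")[:4], ("A", "B", "C"), (1, 3, 5))


def brute_force_exact_mcnemar(b: int, c: int) -> float:
    """Independent oracle: doubled upper tail of Binomial(b+c, 1/2) by enumeration."""
    from math import comb

    nd = b + c
    if nd == 0:
        return 1.0
    m = max(b, c)
    tail = sum(comb(nd, x) for x in range(m, nd + 1)) * 0.5**nd
    return min(1.0, 2.0 * tail)


def brute_force_cochran_q(matrix) -> float:
    """Independent oracle: Cochran's Q evaluated term by term from its definition."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    col = [x[:, j].sum() for j in range(k)]
    row = [x[i, :].sum() for i in range(n)]
    grand = sum(col)
    num = k * (k - 1) * sum((cj - grand / k) ** 2 for cj in col)
    den = k * sum(row) - sum(r**2 for r in row)
    return num / den
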