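"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from nanossbd import CaseParams, make_case_fixture


def det_laplace(M: np.ndarray) -> float:
    """Determinant by recursive Laplace expansion (independent oracle)."""
    n = M.shape[0]
    if n == 0:
        return 1.0  # empty-product convention, needed for 1x1 minors
    if n == 1:
        return M[0, 0]
    total = 0.0
    for j in range(n):
        minor = np.delete(np.delete(M, 0, axis=0), j, axis=1)
        total += (-1.0) ** j * M[0, j] * det_laplace(minor)
    return total


def cofactor_inverse(M: np.ndarray) -> np.ndarray:
    """Matrix inverse via the adjugate (cofactor) formula.

    Deliberately naive: O(n!) determinants, usable only for tiny systems,
    and entirely independent of the LU-based solver under test.
    """
    n = M.shape[0]
    det = det_laplace(M)
    cof = np.empty_like(M, dtype=float)
    for i in range(n):
        for j in range(n):
            minor = np.delete(np.delete(M, i, axis=0), j, axis=1)
            cof[i, j] = (-1.0) ** (i + j) * det_laplace(minor)
    return cof.T / det


@pytest.fixture(scope="session")
def case_fixture():
    return make_case_fixture(CaseParams())


@pytest.fixture(scope="session")
def case_params():
    return CaseParams()
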