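"""Chi-square (conditional) independence testing on discrete data.

This kernel backs both phases of the causal discovery pipeline: the
Markov-blanket search uses it to operationalize d-separation, and the
direction-learning phase reuses it to test residual/cause independence.

Conventions
-----------
Variables are integer-coded categorical columns (states ``0..m-1``).  The
conditional test stratifies on the joint state of the conditioning set and
sums per-stratum Pearson statistics and degrees of freedom — the standard
form of the chi-square d-separation test on discrete data.

A test is flagged *unreliable* when the sample is too small for its degrees
of freedom (``n < 5 * dof``, the classic heuristic from constraint-based
structure learning).  Callers treat an unreliable test as "independence not
rejected" so that sparse strata never fabricate edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CITestResult", "chi2_independence", "chi2_conditional", "DegenerateVariableError"]

#: Reliability heuristic: require at least this many samples per degree of freedom.
SAMPLES_PER_DOF = 5

#: Default significance level shared across the pipeline (configurable per call site).
DEFAULT_ALPHA = 0.05


class DegenerateVariableError(ValueError):
    """A tested variable has fewer than two observed states."""


@dataclass(frozen=True)
class CITestResult:
    """Outcome of a (conditional) chi-square independence test.

    ``reliable=False`` means the sample was too small for the test's degrees
    of freedom; by convention such a test never rejects independence.
    """

    x: str
    y: str
    z: tuple[str, ...]
    statistic: float
    dof: int
    p_value: float
    reliable: bool
    n: int

    def rejects(self, alpha: float = DEFAULT_ALPHA) -> bool:
        """True iff independence is rejected at level ``alpha`` by a reliable test."""
        return self.reliable and self.p_value < alpha


def _as_codes(col: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary integer codes to dense 0..k-1 codes over *observed* states."""
    uniq, codes = np.unique(np.asarray(col), return_inverse=True)
    return codes.astype(np.int64), len(uniq)


def _pearson_table(codes_x: np.ndarray, codes_y: np.ndarray, mx: int, my: int) -> tuple[float, int]:
    """Pearson statistic and dof on one contingency table.

    Rows/columns with zero margin are dropped before computing dof, so all
    expected counts are positive.  Returns (0.0, 0) for degenerate tables.
    """
    table = np.bincount(codes_x * my + codes_y, minlength=mx * my).reshape(mx, my).astype(np.float64)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        return 0.0, 0
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, (r - 1) * (c - 1)


def _finalize(x: str, y: str, z: Sequence[str], stat: float, dof: int, n: int) -> CITestResult:
    if dof >= 1:
        p = float(stats.chi2.sf(stat, dof))
        reliable = n >= SAMPLES_PER_DOF * dof
    else:
        # No usable stratum: nothing to test, treat as independence not rejected.
        p, reliable = 1.0, False
    return CITestResult(x=x, y=y, z=tuple(z), statistic=stat, dof=max(dof, 1),
                        p_value=p, reliable=reliable, n=n)


def chi2_independence(x: np.ndarray, y: np.ndarray, *, x_name: str = "x", y_name: str = "y") -> CITestResult:
    """Marginal Pearson chi-square test between two categorical columns.

    Raises :class:`DegenerateVariableError` if either variable has fewer than
    two observed states.
    """
    codes_x, mx = _as_codes(x)
    codes_y, my = _as_codes(y)
    if mx < 2:
        raise DegenerateVariableError(f"variable {x_name!r} has {mx} observed state(s)")
    if my < 2:
        raise DegenerateVariableError(f"variable {y_name!r} has {my} observed state(s)")
    stat, dof = _pearson_table(codes_x, codes_y, mx, my)
    return _finalize(x_name, y_name, (), stat, dof, len(codes_x))


def chi2_conditional(
    x: np.ndarray,
    y: np.ndarray,
    z: Sequence[np.ndarray] | None = None,
    *,
    x_name: str = "x",
    y_name: str = "y",
    z_names: Sequence[str] = (),
) -> CITestResult:
    """Conditional chi-square test of ``x ⟂ y | z`` by stratified summation.

    The statistic and dof are summed over the observed joint states of the
    conditioning set; strata in which either variable is constant contribute
    nothing.  With an empty ``z`` this reduces exactly to
    :func:`chi2_independence`.
    """
    if not z:
        return chi2_independence(x, y, x_name=x_name, y_name=y_name)

    codes_x, mx = _as_codes(x)
    codes_y, my = _as_codes(y)
    if mx < 2:
        raise DegenerateVariableError(f"variable {x_name!r} has {mx} observed state(s)")
    if my < 2:
        raise DegenerateVariableError(f"variable {y_name!r} has {my} observed state(s)")

    # Joint stratum code over the conditioning set.
    stratum = np.zeros(len(codes_x), dtype=np.int64)
    for col in z:
        codes_z, mz = _as_codes(col)
        stratum = stratum * mz + codes_z

    total_stat, total_dof = 0.0, 0
    order = np.argsort(stratum, kind="stable")
    sorted_strata = stratum[order]
    boundaries = np.flatnonzero(np.diff(sorted_strata)) + 1
    for idx in np.split(order, boundaries):
        sx, sy = codes_x[idx], codes_y[idx]
        stat, dof = _pearson_table(sx, sy, mx, my)
        total_stat += stat
        total_dof += dof

    names = tuple(z_names) if z_names else tuple(f"z{i}" for i in range(len(z)))
    return _finalize(x_name, y_name, names, total_stat, total_dof, len(codes_x))
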