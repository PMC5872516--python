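"""Direction learning: many-to-one causal identification via a discrete ANM.

The direction-learning phase decides which Markov-blanket members are
*direct causes* of the outcome.  Candidate subsets {x1, x2, ...} are merged
into a single converted feature x̄ = g(x1, x2, ...) whose states enumerate
the joint states of its components (mixed-radix, last component varying
fastest, 1-based).  The functional causal model

    y = f(x̄, N),   N independent of x̄

is then fitted in both directions.  ``f`` is estimated as the conditional
mode per x̄ state, and the residual is taken modulo the effect's state count
(cyclic additive noise, the standard discrete-ANM formulation; for a binary
outcome the residual is exactly the XOR noise term).  Residual/cause
independence is judged by the shared chi-square kernel.  A subset is
accepted when the forward residual is independent of x̄ while the backward
fit (x̄ regressed on y) violates independence — the asymmetry that
identifies causal direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ci import SAMPLES_PER_DOF, chi2_independence
from .features import CategoricalFeature, FeatureMatrix
from .markov import MarkovBlanket

__all__ = ["ConvertedFeature", "AnmFit", "CausalResult", "convert", "fit_anm", "discover_causes"]


# ---------------------------------------------------------------------------
# Joint-state conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvertedFeature:
    """x̄ = g(x1, x2, ...): one categorical variable over the joint states.

    Indices are 1-based and enumerate component tuples with the *last*
    component varying fastest: (v1¹, ..., vk¹) -> 1 and
    (v1^{m1}, ..., vk^{mk}) -> m1·m2·...·mk.
    """

    components: tuple[CategoricalFeature, ...]

    @property
    def m_bar(self) -> int:
        out = 1
        for c in self.components:
            out *= c.m
        return out

    @property
    def radices(self) -> tuple[int, ...]:
        return tuple(c.m for c in self.components)

    def encode(self, states: Sequence[int]) -> int:
        """1-based converted index of a tuple of 0-based component states."""
        if len(states) != len(self.components):
            raise ValueError("tuple length does not match component count")
        idx = 0
        for s, c in zip(states, self.components):
            if not 0 <= s < c.m:
                raise ValueError(f"state {s} out of range for {c.name!r}")
            idx = idx * c.m + s
        return idx + 1

    def decode(self, index: int) -> tuple[int, ...]:
        """0-based component states of a 1-based converted index."""
        if not 1 <= index <= self.m_bar:
            raise ValueError(f"index {index} outside 1..{self.m_bar}")
        rem = index - 1
        out = []
        for c in reversed(self.components):
            out.append(rem % c.m)
            rem //= c.m
        return tuple(reversed(out))

    def encode_columns(self, columns: Sequence[np.ndarray]) -> np.ndarray:
        """Vectorized encode of per-component code columns (1-based result)."""
        idx = np.zeros(len(columns[0]), dtype=np.int64)
        for col, c in zip(columns, self.components):
            idx = idx * c.m + np.asarray(col)
        return idx + 1


def convert(components: Sequence[CategoricalFeature]) -> ConvertedFeature:
    """Build the converted feature for an ordered list of components."""
    if len(components) == 0:
        raise ValueError("conversion needs at least one component")
    return ConvertedFeature(components=tuple(components))


# ---------------------------------------------------------------------------
# Additive-noise fit
# ---------------------------------------------------------------------------

@dataclass
class AnmFit:
    """One directed fit y = f(x̄) + N (mod m_y) with its residual test."""

    direction: str                 # "forward" | "backward"
    f_hat: dict[int, int]          # x̄ state -> fitted y state
    residuals: np.ndarray          # per-row residual, in 0..m_y-1
    independence_p: float
    reliable: bool
    zero_support_states: tuple[int, ...] = ()


def fit_anm(x_codes: np.ndarray, y_codes: np.ndarray, m_y: int,
            direction: str = "forward",
            x_states: Sequence[int] | None = None) -> AnmFit:
    """Fit the discrete ANM of ``y`` on ``x`` and test residual independence.

    ``f_hat`` is the conditional mode of y per x state (ties to the smaller
    state).  Residuals are (y - f_hat(x)) mod m_y.  States of x never
    observed keep the global mode (flagged).  A constant residual is
    trivially independent of everything (p = 1).
    """
    x = np.asarray(x_codes)
    y = np.asarray(y_codes)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("x and y must be non-empty and equally long")

    global_mode = int(np.bincount(y, minlength=m_y).argmax())
    f_hat: dict[int, int] = {}
    observed = {int(s) for s in np.unique(x)}
    for state in sorted(observed):
        f_hat[state] = int(np.bincount(y[x == state], minlength=m_y).argmax())
    # Declared x states never observed fall back to the global mode (flagged).
    zero_support = [s for s in (x_states or ()) if int(s) not in observed]
    for s in zero_support:
        f_hat[int(s)] = global_mode

    fitted = np.asarray([f_hat.get(int(s), global_mode) for s in x])
    residuals = np.mod(y - fitted, m_y)

    if len(np.unique(residuals)) < 2 or len(np.unique(x)) < 2:
        # Constant residual (or a single observed x state): independence holds trivially.
        return AnmFit(direction=direction, f_hat=f_hat, residuals=residuals,
                      independence_p=1.0, reliable=True,
                      zero_support_states=tuple(zero_support))
    test = chi2_independence(residuals, x, x_name="residual", y_name="xbar")
    return AnmFit(direction=direction, f_hat=f_hat, residuals=residuals,
                  independence_p=test.p_value, reliable=test.reliable,
                  zero_support_states=tuple(zero_support))


# ---------------------------------------------------------------------------
# Cause discovery over blanket subsets
# ---------------------------------------------------------------------------

@dataclass
class CausalResult:
    """The accepted many-to-one structure {x1, x2, ...} -> y (if any)."""

    causes: tuple[str, ...]
    forward_p: float
    backward_p: float
    accepted: bool
    search_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accepted and not self.causes:
            raise ValueError("accepted result must name its causes")


def discover_causes(
    matrix: FeatureMatrix,
    blanket: MarkovBlanket,
    alpha: float = 0.05,
    max_set_size: int = 4,
) -> CausalResult:
    """Search blanket subsets for the unique accepted many-to-one structure.

    Subsets are enumerated by increasing cardinality, lexicographically
    within a cardinality.  Subsets whose converted feature is too fine for
    the sample (n < 5·(m_bar - 1)) are skipped as unreliable.  A subset is
    admissible when the forward residual test does not reject (p > alpha,
    reliable) and the backward test rejects (p <= alpha, reliable).

    A many-to-one structure is only tenable for the *unique* set of *all*
    causes.  Hence the decision is taken at the maximal admissible
    cardinality (an admissible proper subset merely means the omitted
    causes' influence escaped detection inside the noise term), and if more
    than one subset of that cardinality is admissible, the evidence is
    ambiguous and no structure is claimed (accepted=False, logged as
    ambiguous).  An empty result is valid.
    """
    n = matrix.n
    members = sorted(blanket.members)
    log: list[dict] = []
    admissible_sets: list[tuple[tuple[str, ...], float, float]] = []

    y = np.asarray(matrix.y)
    m_y = int(y.max()) + 1 if len(y) else 2

    for k in range(1, min(max_set_size, len(members)) + 1):
        for names in itertools.combinations(members, k):
            comps = [matrix.feature(f) for f in names]
            conv = convert(comps)
            entry: dict = {"subset": names, "m_bar": conv.m_bar}
            if n < SAMPLES_PER_DOF * (conv.m_bar - 1):
                entry["skipped"] = "m_bar too fine for sample"
                log.append(entry)
                continue
            xbar = conv.encode_columns([matrix.column(f) for f in names])
            forward = fit_anm(xbar, y, m_y, direction="forward")
            backward = fit_anm(y, xbar - 1, conv.m_bar, direction="backward")
            entry["forward_p"] = forward.independence_p
            entry["backward_p"] = backward.independence_p
            entry["forward_reliable"] = forward.reliable
            entry["backward_reliable"] = backward.reliable
            admissible = (
                forward.reliable and forward.independence_p > alpha
                and backward.reliable and backward.independence_p <= alpha
            )
            entry["admissible"] = admissible
            log.append(entry)
            if admissible:
                admissible_sets.append(
                    (names, forward.independence_p, backward.independence_p))

    if not admissible_sets:
        return CausalResult(causes=(), forward_p=float("nan"), backward_p=float("nan"),
                            accepted=False, search_log=log)
    k_max = max(len(s[0]) for s in admissible_sets)
    top = [s for s in admissible_sets if len(s[0]) == k_max]
    if len(top) > 1:
        log.append({"subset": (), "m_bar": 0,
                    "skipped": f"ambiguous: {len(top)} admissible sets of size {k_max}"})
        return CausalResult(causes=(), forward_p=float("nan"), backward_p=float("nan"),
                            accepted=False, search_log=log)
    names, forward_p, backward_p = top[0]
    return CausalResult(causes=names, forward_p=forward_p, backward_p=backward_p,
                        accepted=True, search_log=log)
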