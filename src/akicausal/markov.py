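"""Markov-blanket discovery for the outcome (structure-learning phase).

An interleaved grow/shrink (IAMB-style) search driven by the chi-square
conditional-independence kernel:

* grow — among candidates dependent on the outcome given the current
  blanket, admit the one with the smallest p-value.  The admission scan runs
  over every remaining candidate simultaneously, so the threshold is
  Bonferroni-corrected (alpha / #candidates) to keep false admissions out on
  wide matrices.
* shrink — after each admission, remove any member that is independent of
  the outcome given the rest of the blanket (conditioning sets capped at
  ``max_cond_size``; when the blanket is larger, the cap-sized subset most
  associated with the outcome is used).

Features removed by the shrink pass are barred from re-admission: the tests
are deterministic, so re-admitting a removed borderline candidate would loop
forever.  Ties on p-values break lexicographically on feature name, making
the result invariant to column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ci import CITestResult, DegenerateVariableError, chi2_conditional, chi2_independence
from .features import FeatureMatrix

__all__ = ["MarkovBlanket", "TraceEvent", "learn_markov_blanket"]


@dataclass(frozen=True)
class TraceEvent:
    action: str  # "admit" | "remove"
    feature: str
    test: CITestResult


@dataclass
class MarkovBlanket:
    target: str
    members: set[str]
    trace: list[TraceEvent] = field(default_factory=list)

    def replay(self) -> set[str]:
        """Re-apply the trace; must reproduce the membership."""
        out: set[str] = set()
        for ev in self.trace:
            if ev.action == "admit":
                out.add(ev.feature)
            elif ev.action == "remove":
                out.discard(ev.feature)
        return out


def _conditioning_set(others: list[str], marginal_p: dict[str, float], cap: int) -> list[str]:
    """Blanket members to condition on: the <=cap most outcome-associated."""
    if len(others) <= cap:
        return sorted(others)
    ranked = sorted(others, key=lambda f: (marginal_p[f], f))
    return sorted(ranked[:cap])


def learn_markov_blanket(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    max_cond_size: int = 3,
) -> MarkovBlanket:
    """Discover the Markov blanket of the outcome in a feature matrix.

    Raises ``ValueError`` on degenerate input (constant outcome or a
    single-row matrix).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if max_cond_size < 1:
        raise ValueError("max_cond_size must be >= 1")
    if matrix.n < 2:
        raise ValueError("matrix must have at least two rows")
    y = np.asarray(matrix.y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; no blanket is identifiable")

    # Features that are constant in-sample can never show dependence; skip them.
    usable: list[str] = []
    marginal_p: dict[str, float] = {}
    for name in matrix.feature_names:
        col = matrix.column(name)
        if len(np.unique(col)) < 2:
            continue
        usable.append(name)
        marginal_p[name] = chi2_independence(col, y, x_name=name, y_name="y").p_value

    members: list[str] = []
    banned: set[str] = set()
    trace: list[TraceEvent] = []

    for _ in range(2 * len(usable) + 1):
        # --- grow: scan all remaining candidates given the current blanket
        candidates = [f for f in usable if f not in members and f not in banned]
        if not candidates:
            break
        threshold = alpha / len(candidates)
        best: tuple[float, str, CITestResult] | None = None
        for name in candidates:
            cond = _conditioning_set(members, marginal_p, max_cond_size)
            test = chi2_conditional(
                matrix.column(name), y, [matrix.column(c) for c in cond],
                x_name=name, y_name="y", z_names=cond,
            )
            if test.reliable and test.p_value < threshold:
                key = (test.p_value, name)
                if best is None or key < (best[0], best[1]):
                    best = (test.p_value, name, test)
        if best is None:
            break
        members.append(best[1])
        members.sort()
        trace.append(TraceEvent("admit", best[1], best[2]))

        # --- shrink: re-test every member against the rest of the blanket
        changed = True
        while changed:
            changed = False
            for name in list(members):
                others = [f for f in members if f != name]
                cond = _conditioning_set(others, marginal_p, max_cond_size)
                test = chi2_conditional(
                    matrix.column(name), y, [matrix.column(c) for c in cond],
                    x_name=name, y_name="y", z_names=cond,
                )
                if not test.rejects(alpha):
                    members.remove(name)
                    banned.add(name)
                    trace.append(TraceEvent("remove", name, test))
                    changed = True

    return MarkovBlanket(target="y", members=set(members), trace=trace)
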