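"""Odds-ratio verification of discovered cause combinations.

Every non-empty exposure profile over the k discovered causes (2^k - 1
masks; 15 for k = 4) is cross-tabulated against the outcome and summarized
as an odds ratio with a 95% Wald confidence interval on the log scale.  The
default exposure reading is *exact-profile*: a row is exposed when it
matches the mask on every cause (bit 1 = "yes", bit 0 = "no"), so the 2^k
masks partition the cohort.  An "at-least" reading (bit-1 causes present,
the rest free) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import FeatureMatrix

__all__ = ["OrResult", "combination_exposure", "odds_ratio", "combination_table"]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class OrResult:
    """One exposure-profile row of the combination table."""

    mask: tuple[int, ...]
    a: int  # exposed cases
    b: int  # exposed controls
    c: int  # unexposed cases
    d: int  # unexposed controls
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane: bool

    @property
    def label(self) -> str:
        return "".join(str(b) for b in self.mask)


def combination_exposure(
    matrix: FeatureMatrix,
    causes: Sequence[str],
    mask: Sequence[int],
    mode: str = "exact",
) -> np.ndarray:
    """Binary exposure vector for one mask over the cause features.

    ``mode="exact"``: exposed iff the row matches the mask on *all* causes.
    ``mode="at-least"``: exposed iff every mask-1 cause is "yes" (others free).
    """
    if len(mask) != len(causes):
        raise ValueError("mask length must equal the number of causes")
    if not any(mask):
        raise ValueError("the all-zero mask is not an exposure profile")
    if mode not in ("exact", "at-least"):
        raise ValueError(f"unknown exposure mode {mode!r}")

    exposed = np.ones(matrix.n, dtype=bool)
    for bit, name in zip(mask, causes):
        feat = matrix.feature(name)
        yes = matrix.column(name) == feat.index_of("yes")
        if bit:
            exposed &= yes
        elif mode == "exact":
            exposed &= ~yes
    return exposed.astype(np.int8)


def odds_ratio(exposure: np.ndarray, outcome: np.ndarray,
               mask: Sequence[int] = ()) -> OrResult:
    """OR = (a·d)/(b·c) of a 2x2 exposure/outcome table with 95% Wald CI.

    When any cell is zero the Haldane-Anscombe correction (+0.5 to every
    cell) is applied, keeping the OR and both CI bounds finite.
    """
    exposure = np.asarray(exposure)
    outcome = np.asarray(outcome)
    if len(exposure) == 0 or len(exposure) != len(outcome):
        raise ValueError("exposure and outcome must be non-empty and equally long")

    a = int(np.sum((exposure == 1) & (outcome == 1)))
    b = int(np.sum((exposure == 1) & (outcome == 0)))
    c = int(np.sum((exposure == 0) & (outcome == 1)))
    d = int(np.sum((exposure == 0) & (outcome == 0)))

    haldane = min(a, b, c, d) == 0
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if haldane else (a, b, c, d)
    or_value = (aa * dd) / (bb * cc)
    se = math.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    log_or = math.log(or_value)
    return OrResult(
        mask=tuple(int(x) for x in mask),
        a=a, b=b, c=c, d=d,
        odds_ratio=or_value,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        haldane=haldane,
    )


def _mask_order_key(mask: tuple[int, ...]) -> tuple[int, int]:
    """Sort key: combination size, then binary value of the reversed mask."""
    reversed_value = sum(bit << i for i, bit in enumerate(mask))
    return (sum(mask), reversed_value)


def combination_table(
    matrix: FeatureMatrix,
    causes: Sequence[str],
    mode: str = "exact",
) -> list[OrResult]:
    """All 2^k - 1 non-empty exposure-profile odds ratios, deterministic order."""
    k = len(causes)
    if not 1 <= k <= 8:
        raise ValueError("combination table supports 1..8 causes")
    masks = [
        tuple((value >> (k - 1 - i)) & 1 for i in range(k))
        for value in range(1, 2 ** k)
    ]
    masks.sort(key=_mask_order_key)
    outcome = np.asarray(matrix.y)
    return [
        odds_ratio(combination_exposure(matrix, causes, mask, mode=mode), outcome, mask=mask)
        for mask in masks
    ]
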