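"""Relational (Brass logit) life tables and cohort survivorship ratios.

A projected life expectancy at birth must be expanded into a full abridged
life table before it can drive a cohort-component projection.  This module
uses the Brass relational system: survivorship at each age is tied to a
*standard* schedule through

    logit(l'_x) = alpha + beta * logit(l_x),      logit(p) = 0.5 * ln((1-p)/p)

so a single level parameter ``alpha`` (with slope ``beta`` fixed at 1)
sweeps out a one-parameter family of life tables around the standard.
``match_e0`` solves for the ``alpha`` whose table has a requested life
expectancy at birth, by bisection; lower ``alpha`` means higher survival,
so ``alpha`` decreases as the target e0 rises.

The bundled standard schedule is synthetic (a smooth survivorship column
with a South-Asian-type age pattern); it can be replaced by any published
standard by editing one CSV.

Life-table arithmetic follows the usual abridged conventions: person-years
``nLx`` by trapezoid over 5-year groups, with a separation factor for the
infant segment of the 0-4 group, and the open 80+ interval closed with the
standard's central death rate ``m80``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StandardSchedule",
    "AbridgedLifeTable",
    "SurvivalRatios",
    "LIFETABLE_AGES",
    "brass_logit",
    "logit",
    "inverse_logit",
    "build_abridged",
    "match_e0",
    "survival_ratios",
]

# Exact ages of the survivorship column: 0, 1, then 5-year steps to 80.
LIFETABLE_AGES: np.ndarray = np.array(
    [0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80]
)


def logit(p):
    """Demographers' half-logit, 0.5 * ln((1-p)/p); decreasing in p."""
    p = np.asarray(p, dtype=float)
    return 0.5 * np.log((1.0 - p) / p)


def inverse_logit(y):
    y = np.asarray(y, dtype=float)
    return 1.0 / (1.0 + np.exp(2.0 * y))


@dataclass(frozen=True)
class StandardSchedule:
    """A standard survivorship column l(x) with l(0) = 1, plus the central
    death rate of the open 80+ interval used to close derived tables."""

    ages: np.ndarray
    lx: np.ndarray
    m80: float
    sex: str = "all"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        lx = np.asarray(self.lx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lx", lx)
        if ages.shape != LIFETABLE_AGES.shape or np.any(ages != LIFETABLE_AGES):
            raise ValueError(f"ages must be exactly {LIFETABLE_AGES.tolist()}")
        if lx[0] != 1.0:
            raise ValueError("standard must be normalized to l(0) = 1")
        if np.any(np.diff(lx) >= 0):
            raise ValueError("l(x) must be strictly decreasing")
        if lx[-1] <= 0:
            raise ValueError("l(80) must remain positive")
        if self.m80 <= 0:
            raise ValueError("m80 must be positive")

    @property
    def e0(self) -> float:
        return build_abridged(self.lx, self.m80).e0


@dataclass(frozen=True)
class AbridgedLifeTable:
    """Abridged life-table columns on 5-year groups 0-4 ... 75-79, 80+.

    ``lx`` holds survivorship at the group lower bounds, ``nLx`` the
    person-years lived in each group, ``Tx`` the person-years remaining and
    ``ex`` the remaining expectancy at each group start.
    """

    x_start: np.ndarray
    lx: np.ndarray
    nLx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    # Brass level parameter used to build the table, when it came from
    # match_e0; None for directly constructed tables.
    alpha: float | None = None

    def __post_init__(self) -> None:
        for name in ("x_start", "lx", "nLx", "Tx", "ex"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.x_start) == len(self.lx) == len(self.nLx) == len(self.Tx) == len(self.ex)):
            raise ValueError("all columns must have equal length")
        if np.any(np.diff(self.lx) > 0):
            raise ValueError("l(x) must be non-increasing")
        if np.any(self.nLx <= 0):
            raise ValueError("nLx must be positive")

    @property
    def e0(self) -> float:
        """Life expectancy at birth, T0 / l0."""
        return float(self.Tx[0] / self.lx[0])

    @property
    def n_groups(self) -> int:
        return len(self.nLx)


def brass_logit(lx, alpha: float, beta: float = 1.0) -> np.ndarray:
    """Transform a survivorship column through the Brass relational system.

    ``alpha = 0, beta = 1`` is the identity; negative ``alpha`` raises
    survival at every interior age.  The radix l(0) = 1 is preserved.
    """
    lx = np.asarray(lx, dtype=float)
    interior = lx[1:] if lx[0] == 1.0 else lx
    if np.any(interior <= 0) or np.any(interior >= 1):
        raise ValueError("interior l(x) must lie strictly inside (0, 1)")
    out = lx.copy()
    if lx[0] == 1.0:
        out[1:] = inverse_logit(alpha + beta * logit(lx[1:]))
    else:
        out = inverse_logit(alpha + beta * logit(lx))
    return out


def build_abridged(lx, m80: float, a0: float = 0.3) -> AbridgedLifeTable:
    """Assemble an abridged life table from l(x) on the standard age grid.

    ``lx`` must cover ages 0, 1, 5, ..., 80.  Person-years in the 0-4 group
    use the separation factor ``a0`` for the infant year
    (``1L0 = a0*l0 + (1-a0)*l1``) and a trapezoid for ages 1-4; closed
    5-year groups use plain trapezoids; the open interval is
    ``L80 = l80 / m80``.
    """
    lx = np.asarray(lx, dtype=float)
    if lx.shape != LIFETABLE_AGES.shape:
        raise ValueError("l(x) must be given on ages 0, 1, 5, ..., 80")
    if np.any(np.diff(lx) > 0):
        raise ValueError("l(x) must be non-increasing")
    if m80 <= 0:
        raise ValueError("m80 must be positive")
    if not 0.0 <= a0 <= 1.0:
        raise ValueError("separation factor a0 must lie in [0, 1]")

    l0, l1 = lx[0], lx[1]
    l5plus = lx[2:]  # ages 5, 10, ..., 80
    L0 = (a0 * l0 + (1.0 - a0) * l1) + 4.0 * (l1 + l5plus[0]) / 2.0
    closed = 5.0 * (l5plus[:-1] + l5plus[1:]) / 2.0  # groups 5-9 ... 75-79
    L80 = lx[-1] / m80
    nLx = np.concatenate([[L0], closed, [L80]])

    x_start = np.arange(0, 85, 5, dtype=float)
    l_bounds = np.concatenate([[l0], l5plus])
    Tx = nLx[::-1].cumsum()[::-1]
    ex = Tx / l_bounds
    return AbridgedLifeTable(x_start=x_start, lx=l_bounds, nLx=nLx, Tx=Tx, ex=ex)


def match_e0(
    target_e0: float,
    standard: StandardSchedule,
    *,
    alpha_lo: float = -2.0,
    alpha_hi: float = 2.0,
    tol: float = 0.01,
    max_iter: int = 200,
    a0: float = 0.3,
) -> AbridgedLifeTable:
    """Find the Brass-level life table whose e0 matches ``target_e0``.

    Bisection on ``alpha`` (slope fixed at 1) until the table's life
    expectancy is within ``tol`` years (default 0.01) of the target.
    Raises if the target lies outside the range achievable for
    ``alpha`` in ``[alpha_lo, alpha_hi]``.
    """

    def table_at(alpha: float) -> AbridgedLifeTable:
        table = build_abridged(brass_logit(standard.lx, alpha), standard.m80, a0=a0)
        return replace(table, alpha=alpha)

    # e0 is decreasing in alpha
    e_hi = table_at(alpha_lo).e0
    e_lo = table_at(alpha_hi).e0
    if not e_lo <= target_e0 <= e_hi:
        raise ValueError(
            f"target e0 {target_e0:.2f} outside achievable range "
            f"[{e_lo:.2f}, {e_hi:.2f}] for alpha in [{alpha_lo}, {alpha_hi}]"
        )
    lo, hi = alpha_lo, alpha_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        table = table_at(mid)
        if abs(table.e0 - target_e0) < tol:
            return table
        if table.e0 > target_e0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("bisection failed to converge; widen tol or alpha range")


@dataclass(frozen=True)
class SurvivalRatios:
    """Five-year cohort survivorship proportions derived from a life table.

    ``S_birth`` takes births occurring during a 5-year step into the 0-4
    group at its end; ``S[i]`` advances closed group i to group i+1;
    ``S_open`` advances the pooled 75-79 and 80+ groups into 80+
    (``T80/T75``).  All ratios lie in (0, 1].
    """

    S_birth: float
    S: np.ndarray
    S_open: float

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        ratios = np.concatenate([[self.S_birth], S, [self.S_open]])
        if np.any(ratios <= 0) or np.any(ratios > 1.0 + 1e-12):
            raise ValueError("survival ratios must lie in (0, 1]")


def survival_ratios(table: AbridgedLifeTable) -> SurvivalRatios:
    """Compute projection survivorship ratios from an abridged life table.

    Works for any number of groups (the last being open):
    ``S_birth = nL0 / (5 l0)``, ``S[i] = nL[i+1] / nL[i]`` for closed
    groups, and ``S_open = T[last] / T[last-1]``.
    """
    nLx, Tx = table.nLx, table.Tx
    if np.any(nLx == 0):
        raise ValueError("zero person-years in a group")
    s_birth = float(nLx[0] / (5.0 * table.lx[0]))
    closed = nLx[1:-1] / nLx[:-2]
    s_open = float(Tx[-1] / Tx[-2])
    return SurvivalRatios(S_birth=s_birth, S=np.minimum(closed, 1.0), S_open=s_open)
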