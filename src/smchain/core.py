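"""Core model: decision cells, ring chains, stationary occupancies, predictive ability.

A decision chain is modelled as a biased random walk on a ring of *cells*.
Each cell is either LIGHT (enough information for deliberation to dominate)
or DARK (uncertainty; conservative primary emotions dominate).  In a LIGHT
cell the agent advances with probability ``p_r`` (deliberative predictive
ability), in a DARK cell with probability ``p_e1`` (primary-emotion
predictive ability); otherwise it retreats to the previous cell.  A long
road with a repeating cell pattern reduces to a cyclic chain over one
period of the pattern, whose stationary distribution gives the *effective*
weight of each mechanism — generally different from the naive cell
fraction, because hard-to-cross DARK cells trap the walker.

Somatic markers (experience-dependent secondary emotions) can override the
local mechanism: with frequency ``beta`` the forward probability becomes
``p_e2`` instead of the local one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "Cell",
    "CellPattern",
    "ConfusionMatrix",
    "DecisionProfile",
    "DegenerateChainError",
    "EffectiveStats",
    "RingChain",
    "StationaryOccupancy",
    "build_ring_chain",
    "effective_stats",
    "effective_usage",
    "forward_probability",
    "linear_predictive_ability",
    "nonlinear_predictive_ability",
    "predictive_ability_from_confusion",
    "sm_linear_benefit_condition",
    "stationary_distribution",
    "summarize",
]

_ROW_SUM_TOL = 1e-12
_PI_TOL = 1e-10


class DegenerateChainError(ValueError):
    """A forward probability of exactly 0 or 1 breaks irreducibility of the ring."""


class Cell(str, Enum):
    """Kind of a decision cell: LIGHT (deliberation) or DARK (primary emotions)."""

    LIGHT = "L"
    DARK = "D"


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class DecisionProfile:
    """Predictive abilities of the three decision mechanisms.

    Parameters
    ----------
    p_r : float
        Deliberative (rational) predictive ability, the probability of a
        correct forward move in a LIGHT cell.
    p_e1 : float
        Primary-emotion predictive ability, the probability of a correct
        forward move in a DARK cell.  Typically low (cautious).
    p_e2 : float, optional
        Somatic-marker (secondary-emotion) predictive ability.  May be
        absent for an agent without somatic markers.
    beta : float, default 0.0
        Frequency with which somatic markers override the local mechanism.
        Requires ``p_e2`` when positive.
    """

    p_r: float
    p_e1: float
    p_e2: float | None = None
    beta: float = 0.0

    def __post_init__(self) -> None:
        _check_unit("p_r", self.p_r)
        _check_unit("p_e1", self.p_e1)
        _check_unit("beta", self.beta)
        if self.p_e2 is not None:
            _check_unit("p_e2", self.p_e2)
        if self.beta > 0 and self.p_e2 is None:
            raise ValueError("beta > 0 requires p_e2 to be set")

    def require_sm(self) -> float:
        """Return ``p_e2``, raising if the profile has no somatic markers."""
        if self.p_e2 is None:
            raise ValueError("somatic-marker computation requires p_e2")
        return self.p_e2

    def local(self, cell: Cell) -> float:
        """Forward probability of the mechanism that dominates ``cell``."""
        return self.p_r if cell is Cell.LIGHT else self.p_e1


@dataclass(frozen=True)
class CellPattern:
    """Ordered sequence of LIGHT/DARK cells; one period of the repeating road."""

    cells: tuple[Cell, ...]

    def __post_init__(self) -> None:
        if len(self.cells) == 0:
            raise ValueError("cell pattern must be nonempty")
        if not all(isinstance(c, Cell) for c in self.cells):
            raise TypeError("cells must be Cell members")

    @classmethod
    def from_string(cls, text: str) -> "CellPattern":
        """Parse a pattern literal over {L, D}, case-insensitively (e.g. ``\"LLD\"``)."""
        try:
            return cls(tuple(Cell(ch) for ch in text.upper()))
        except ValueError:
            raise ValueError(
                f"invalid pattern {text!r}: only 'L' and 'D' are allowed"
            ) from None

    @property
    def alpha(self) -> float:
        """Fraction of LIGHT cells — the naive weight of deliberation."""
        return sum(c is Cell.LIGHT for c in self.cells) / len(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def __str__(self) -> str:
        return "".join(c.value for c in self.cells)


@dataclass(frozen=True)
class RingChain:
    """Cyclic birth-death chain: state ``i`` advances to ``i+1 (mod n)`` with
    probability ``forward_prob[i]``, otherwise retreats to ``i-1 (mod n)``."""

    forward_prob: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.forward_prob, dtype=float)
        t = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "forward_prob", q)
        object.__setattr__(self, "transition", t)
        if q.ndim != 1 or q.size < 3:
            raise ValueError("ring chain needs at least 3 states")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("forward probabilities must lie in [0, 1]")
        if t.shape != (q.size, q.size):
            raise ValueError("transition matrix shape does not match forward_prob")
        if not np.allclose(t.sum(axis=1), 1.0, rtol=0, atol=_ROW_SUM_TOL):
            raise ValueError("transition rows must sum to 1")

    @property
    def size(self) -> int:
        return self.forward_prob.size


@dataclass(frozen=True)
class StationaryOccupancy:
    """Normalized long-run visit frequencies over the states of a ring chain."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if np.any(pi < -_PI_TOL):
            raise ValueError("stationary occupancies must be nonnegative")
        if abs(pi.sum() - 1.0) > _PI_TOL:
            raise ValueError("stationary occupancies must sum to 1")

    def __len__(self) -> int:
        return self.pi.size


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-class confusion counts: a (correct-positive), b (incorrect-negative),
    c (incorrect-positive), d (correct-negative)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def _rate(self, count: float) -> float:
        if self.total <= 0:
            raise ValueError("confusion matrix has zero total count")
        return count / self.total

    @property
    def a_star(self) -> float:
        return self._rate(self.a)

    @property
    def b_star(self) -> float:
        return self._rate(self.b)

    @property
    def c_star(self) -> float:
        return self._rate(self.c)

    @property
    def d_star(self) -> float:
        return self._rate(self.d)


@dataclass(frozen=True)
class EffectiveStats:
    """Stationary-state summary of a decision chain.

    ``usage`` maps mechanism names ("R", "E1", and "E2" when somatic
    markers are active) to their effective stationary frequency;
    ``p_x_nonlinear`` is the stationary-weighted forward probability and
    ``p_x_linear`` the naive additive mixture; ``delta`` their difference.
    """

    usage: Mapping[str, float]
    p_x_nonlinear: float
    p_x_linear: float
    pi: StationaryOccupancy = field(repr=False)

    @property
    def delta(self) -> float:
        return self.p_x_nonlinear - self.p_x_linear


def forward_probability(cell: Cell, profile: DecisionProfile, use_sm: bool = False) -> float:
    """Probability of a correct forward move in ``cell``.

    Without somatic markers this is the local mechanism's ability
    (``p_r`` in LIGHT, ``p_e1`` in DARK).  With ``use_sm`` the markers
    override the local mechanism with frequency ``beta``, giving the
    mixture ``(1 - beta) * p_local + beta * p_e2``.
    """
    local = profile.local(cell)
    if not use_sm:
        return local
    p_e2 = profile.require_sm()
    return (1.0 - profile.beta) * local + profile.beta * p_e2


def build_ring_chain(
    pattern: CellPattern,
    profile: DecisionProfile,
    use_sm: bool = False,
    sm_mode: str = "mixture",
) -> RingChain:
    """Build the cyclic chain over one period of ``pattern``.

    ``sm_mode`` selects how somatic markers enter the chain when
    ``use_sm`` is on:

    - ``"mixture"`` (default): each cell's forward probability is the
      per-decision mixture ``(1 - beta) * p_local + beta * p_e2``.
    - ``"subcell"``: each cell is split spatially into a local half-cell
      followed by a marker half-cell, doubling the ring; this realizes
      the half-and-half override and therefore requires ``beta = 1/2``.
    """
    n = len(pattern)
    if n < 3:
        raise ValueError(
            f"ring chain needs a pattern of length >= 3 (got {n}): "
            "forward and backward neighbors must be distinct"
        )
    if sm_mode not in ("mixture", "subcell"):
        raise ValueError(f"unknown sm_mode {sm_mode!r}")
    if use_sm and sm_mode == "subcell":
        p_e2 = profile.require_sm()
        if profile.beta != 0.5:
            raise ValueError("subcell mode realizes a half-and-half split; beta must be 1/2")
        q = np.empty(2 * n)
        q[0::2] = [profile.local(c) for c in pattern.cells]
        q[1::2] = p_e2
    else:
        q = np.array([forward_probability(c, profile, use_sm) for c in pattern.cells])
    return ring_chain_from_forward(q)


def ring_chain_from_forward(q: np.ndarray) -> RingChain:
    """Assemble a :class:`RingChain` directly from forward probabilities."""
    q = np.asarray(q, dtype=float)
    n = q.size
    if n < 3:
        raise ValueError("ring chain needs at least 3 states")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("forward probabilities must lie in [0, 1]")
    t = np.zeros((n, n))
    idx = np.arange(n)
    t[idx, (idx + 1) % n] = q
    t[idx, (idx - 1) % n] = 1.0 - q
    return RingChain(forward_prob=q, transition=t)


def stationary_distribution(chain: RingChain) -> StationaryOccupancy:
    """Solve the unique stationary distribution of an irreducible ring chain.

    Solves the linear system ``(T' - I) pi = 0`` with one equation replaced
    by the normalization ``sum(pi) = 1`` — an exact small-system solve with
    no iteration-convergence ambiguity.

    Raises
    ------
    DegenerateChainError
        If any forward probability is exactly 0 or 1: the ring is then no
        longer irreducible and the stationary vector need not be unique.
    """
    q = chain.forward_prob
    if np.any(q == 0.0) or np.any(q == 1.0):
        raise DegenerateChainError(
            "forward probability of 0 or 1 makes the ring reducible; "
            "stationary distribution is not unique"
        )
    n = chain.size
    a = chain.transition.T - np.eye(n)
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    return StationaryOccupancy(pi=np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum())


def effective_usage(pi: StationaryOccupancy, pattern: CellPattern) -> dict[str, float]:
    """Stationary usage frequency of each local mechanism.

    The frequency of deliberation ("R") is the total occupancy of LIGHT
    cells; of primary emotions ("E1"), the occupancy of DARK cells.  With
    a flat occupancy this reduces to the cell fractions (alpha, 1 - alpha);
    trapping in DARK cells pushes "E1" above its cell fraction.
    """
    if len(pi) != len(pattern):
        raise ValueError(
            f"occupancy has {len(pi)} states but pattern has {len(pattern)} cells"
        )
    light = np.array([c is Cell.LIGHT for c in pattern.cells])
    r = float(pi.pi[light].sum())
    e1 = float(pi.pi[~light].sum())
    return {"R": r, "E1": e1}


def nonlinear_predictive_ability(pi: StationaryOccupancy, chain: RingChain) -> float:
    """Effective predictive ability: the stationary-weighted forward probability."""
    if len(pi) != chain.size:
        raise ValueError("occupancy and chain dimensions do not match")
    return float(pi.pi @ chain.forward_prob)


def linear_predictive_ability(
    alpha: float, profile: DecisionProfile, use_sm: bool = False
) -> float:
    """Additive-mixture predictive ability, treating decisions as independent.

    Without somatic markers: ``alpha * p_r + (1 - alpha) * p_e1``.  With
    them: ``beta * p_e2 + (1 - beta) * (alpha * p_r + (1 - alpha) * p_e1)``.
    """
    _check_unit("alpha", alpha)
    base = alpha * profile.p_r + (1.0 - alpha) * profile.p_e1
    if not use_sm:
        return base
    p_e2 = profile.require_sm()
    return profile.beta * p_e2 + (1.0 - profile.beta) * base


def sm_linear_benefit_condition(profile: DecisionProfile, alpha: float) -> bool:
    """Whether somatic markers help under the independent-decisions (linear) view.

    True iff ``p_e2`` strictly exceeds the no-marker mixture
    ``alpha * p_r + (1 - alpha) * p_e1``; ties count as no benefit.
    """
    p_e2 = profile.require_sm()
    return p_e2 > linear_predictive_ability(alpha, profile, use_sm=False)


def predictive_ability_from_confusion(cm: ConfusionMatrix) -> float:
    """Predictive ability as the accuracy of a two-class confusion matrix, a* + d*."""
    return cm.a_star + cm.d_star


def effective_stats(
    pattern: CellPattern,
    profile: DecisionProfile,
    use_sm: bool = False,
    sm_mode: str = "mixture",
) -> EffectiveStats:
    """Build the ring chain, solve it, and summarize the stationary state."""
    chain = build_ring_chain(pattern, profile, use_sm=use_sm, sm_mode=sm_mode)
    pi = stationary_distribution(chain)
    p_x = nonlinear_predictive_ability(pi, chain)
    p_lin = linear_predictive_ability(pattern.alpha, profile, use_sm=use_sm)
    light = np.array([c is Cell.LIGHT for c in pattern.cells])
    if not use_sm:
        occ = pi.pi
        usage = {"R": float(occ[light].sum()), "E1": float(occ[~light].sum())}
    elif sm_mode == "mixture":
        # per cell, the local mechanism acts with weight (1 - beta), markers with beta
        occ = pi.pi
        usage = {
            "R": float((1.0 - profile.beta) * occ[light].sum()),
            "E1": float((1.0 - profile.beta) * occ[~light].sum()),
            "E2": float(profile.beta),
        }
    else:  # subcell: even states are local halves, odd states marker halves
        occ = pi.pi
        local_occ = occ[0::2]
        usage = {
            "R": float(local_occ[light].sum()),
            "E1": float(local_occ[~light].sum()),
            "E2": float(occ[1::2].sum()),
        }
    return EffectiveStats(usage=usage, p_x_nonlinear=p_x, p_x_linear=p_lin, pi=pi)


def summarize(
    pattern: CellPattern,
    profile: DecisionProfile,
    use_sm: bool = False,
    sm_mode: str = "mixture",
) -> dict:
    """JSON-ready summary of the stationary analysis for one configuration."""
    stats = effective_stats(pattern, profile, use_sm=use_sm, sm_mode=sm_mode)
    return {
        "pattern": str(pattern),
        "alpha": pattern.alpha,
        "profile": {
            "p_r": profile.p_r,
            "p_e1": profile.p_e1,
            "p_e2": profile.p_e2,
            "beta": profile.beta,
        },
        "use_sm": use_sm,
        "sm_mode": sm_mode,
        "pi": stats.pi.pi.tolist(),
        "usage": dict(stats.usage),
        "p_x_nonlinear": stats.p_x_nonlinear,
        "p_x_linear": stats.p_x_linear,
        "delta": stats.delta,
    }
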