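"""Parameter-space exploration of somatic-marker coupling.

The headline phenomenon: locally "defective" somatic markers
(``p_e2 < 1/2``) coupled to an already below-baseline reasoning/primary
emotion system can lift the combined chain *above* baseline — a
losing + losing = winning coupling in the spirit of Parrondo's games.
This module maps the parameter regions where that happens, traces the
sensitivity of the effective ability to ``p_e2``, and locates the
marker-advantage boundary in ``p_e2`` as a function of ``p_r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    Cell,
    CellPattern,
    DecisionProfile,
    build_ring_chain,
    effective_stats,
    nonlinear_predictive_ability,
    stationary_distribution,
)

__all__ = [
    "CouplingRecord",
    "RegionMap",
    "SensitivityCurve",
    "batch_nonlinear_px",
    "compare_sm_effect",
    "positive_coupling_region",
    "sensitivity_curve",
    "sm_advantage_boundary",
]

BASELINE = 0.5


@dataclass(frozen=True)
class CouplingRecord:
    """Linear and non-linear abilities of one parameter point, with and without markers."""

    profile: DecisionProfile
    p_x_no_sm: float
    p_x_with_sm: float
    p_x_linear_no_sm: float
    p_x_linear_with_sm: float

    @property
    def above_baseline(self) -> bool:
        """Combined non-linear system beats the coin-flip baseline of 1/2."""
        return self.p_x_with_sm > BASELINE

    @property
    def paradoxical(self) -> bool:
        """Defective markers + below-baseline base system, yet above-baseline combined."""
        p_e2 = self.profile.p_e2
        return (
            p_e2 is not None
            and p_e2 < BASELINE
            and self.p_x_no_sm < BASELINE
            and self.p_x_with_sm > BASELINE
        )


@dataclass(frozen=True)
class RegionMap:
    """Grid of :class:`CouplingRecord` flags over the (p_r, p_e1) plane at fixed p_e2."""

    p_r_grid: np.ndarray
    p_e1_grid: np.ndarray
    p_e2: float
    beta: float
    pattern: CellPattern
    sm_mode: str
    table: pd.DataFrame = field(repr=False)

    @property
    def paradoxical_count(self) -> int:
        return int(self.table["paradoxical"].sum())

    @property
    def resolution(self) -> tuple[int, int]:
        return (self.p_r_grid.size, self.p_e1_grid.size)

    def metadata(self) -> dict:
        return {
            "p_e2": self.p_e2,
            "beta": self.beta,
            "pattern": str(self.pattern),
            "sm_mode": self.sm_mode,
            "p_r_grid": [float(self.p_r_grid.min()), float(self.p_r_grid.max()), self.p_r_grid.size],
            "p_e1_grid": [float(self.p_e1_grid.min()), float(self.p_e1_grid.max()), self.p_e1_grid.size],
            "deterministic": True,
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class SensitivityCurve:
    """Effective ability vs ``p_e2``, with its finite-difference derivative."""

    p_e2_values: np.ndarray
    p_x_values: np.ndarray
    p_x_linear_values: np.ndarray
    derivative: np.ndarray

    def __post_init__(self) -> None:
        n = self.p_e2_values.size
        if not (self.p_x_values.size == self.p_x_linear_values.size == self.derivative.size == n):
            raise ValueError("curve vectors must have equal length")
        if np.any(np.diff(self.p_e2_values) <= 0):
            raise ValueError("p_e2_values must be strictly increasing")


def _pattern_forward(pattern: CellPattern, p_r, p_e1) -> np.ndarray:
    """Forward-probability vectors (broadcast over parameter arrays) for a pattern."""
    p_r = np.asarray(p_r, dtype=float)
    p_e1 = np.asarray(p_e1, dtype=float)
    cols = [np.where(c is Cell.LIGHT, p_r, p_e1) for c in pattern.cells]
    return np.stack(np.broadcast_arrays(*cols), axis=-1)


def batch_nonlinear_px(q: np.ndarray) -> np.ndarray:
    """Stationary-weighted forward probability for a batch of ring chains.

    ``q`` has shape (..., n); rows with any forward probability exactly 0
    or 1 (degenerate rings) yield NaN.  Uses one stacked linear solve, the
    batched analogue of :func:`smchain.core.stationary_distribution`.
    """
    q = np.asarray(q, dtype=float)
    n = q.shape[-1]
    flat = q.reshape(-1, n)
    out = np.full(flat.shape[0], np.nan)
    ok = np.all((flat > 0.0) & (flat < 1.0), axis=1)
    if ok.any():
        qs = flat[ok]
        m = qs.shape[0]
        idx = np.arange(n)
        t = np.zeros((m, n, n))
        t[:, idx, (idx + 1) % n] = qs
        t[:, idx, (idx - 1) % n] = 1.0 - qs
        a = np.transpose(t, (0, 2, 1)) - np.eye(n)
        a[:, -1, :] = 1.0
        b = np.zeros((m, n, 1))
        b[:, -1, 0] = 1.0
        pi = np.linalg.solve(a, b)[..., 0]
        out[ok] = np.einsum("ij,ij->i", pi, qs)
    return out.reshape(q.shape[:-1])


def compare_sm_effect(
    profile: DecisionProfile, pattern: CellPattern, sm_mode: str = "mixture"
) -> CouplingRecord:
    """Evaluate one parameter point with and without somatic markers."""
    profile.require_sm()
    if not (0.0 < profile.beta <= 1.0):
        raise ValueError("compare_sm_effect requires beta in (0, 1]")
    no_sm = effective_stats(pattern, profile, use_sm=False)
    with_sm = effective_stats(pattern, profile, use_sm=True, sm_mode=sm_mode)
    return CouplingRecord(
        profile=profile,
        p_x_no_sm=no_sm.p_x_nonlinear,
        p_x_with_sm=with_sm.p_x_nonlinear,
        p_x_linear_no_sm=no_sm.p_x_linear,
        p_x_linear_with_sm=with_sm.p_x_linear,
    )


def positive_coupling_region(
    p_r_grid: np.ndarray,
    p_e1_grid: np.ndarray,
    p_e2: float,
    beta: float,
    pattern: CellPattern,
    sm_mode: str = "mixture",
) -> RegionMap:
    """Scan the (p_r, p_e1) plane at fixed ``p_e2`` for paradoxical coupling.

    Each grid point is classified as *paradoxical* when the markers are
    defective (``p_e2 < 1/2``), the base chain is below baseline, and the
    combined chain is above it.  Grid points whose chain is degenerate
    (a forward probability of exactly 0 or 1) carry NaN abilities and are
    never flagged.
    """
    p_r_grid = np.atleast_1d(np.asarray(p_r_grid, dtype=float))
    p_e1_grid = np.atleast_1d(np.asarray(p_e1_grid, dtype=float))
    if p_r_grid.size == 0 or p_e1_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    rr, ee = np.meshgrid(p_r_grid, p_e1_grid, indexing="ij")
    rr, ee = rr.ravel(), ee.ravel()
    q_no = _pattern_forward(pattern, rr, ee)
    if sm_mode == "mixture":
        q_sm = (1.0 - beta) * q_no + beta * p_e2
    elif sm_mode == "subcell":
        if beta != 0.5:
            raise ValueError("subcell mode realizes a half-and-half split; beta must be 1/2")
        n = len(pattern)
        q_sm = np.empty((q_no.shape[0], 2 * n))
        q_sm[:, 0::2] = q_no
        q_sm[:, 1::2] = p_e2
    else:
        raise ValueError(f"unknown sm_mode {sm_mode!r}")
    px_no = batch_nonlinear_px(q_no)
    px_sm = batch_nonlinear_px(q_sm)
    alpha = pattern.alpha
    lin_no = alpha * rr + (1.0 - alpha) * ee
    lin_sm = beta * p_e2 + (1.0 - beta) * lin_no
    valid = ~(np.isnan(px_no) | np.isnan(px_sm))
    above = valid & (px_sm > BASELINE)
    paradox = above & (p_e2 < BASELINE) & (px_no < BASELINE)
    table = pd.DataFrame(
        {
            "p_r": rr,
            "p_e1": ee,
            "p_e2": p_e2,
            "beta": beta,
            "pattern": str(pattern),
            "p_x_no_sm": px_no,
            "p_x_with_sm": px_sm,
            "p_x_linear_no_sm": lin_no,
            "p_x_linear_with_sm": lin_sm,
            "above_baseline": above,
            "paradoxical": paradox,
        }
    )
    return RegionMap(
        p_r_grid=p_r_grid,
        p_e1_grid=p_e1_grid,
        p_e2=p_e2,
        beta=beta,
        pattern=pattern,
        sm_mode=sm_mode,
        table=table,
    )


def sensitivity_curve(
    profile: DecisionProfile,
    pattern: CellPattern,
    beta: float,
    p_e2_values: np.ndarray | None = None,
    step: float = 0.025,
    sm_mode: str = "mixture",
) -> SensitivityCurve:
    """Effective ability of the marker agent as ``p_e2`` sweeps a range.

    The derivative is estimated by central differences at interior points
    and one-sided differences at the ends (``numpy.gradient``), at the
    curve's own sampling step.
    """
    if p_e2_values is None:
        if step <= 0:
            raise ValueError("step must be positive")
        p_e2_values = np.arange(0.0, 1.0 + step / 2, step)
    p_e2_values = np.asarray(p_e2_values, dtype=float)
    if p_e2_values.size < 3:
        raise ValueError("need at least 3 points to estimate a derivative")
    q_base = _pattern_forward(pattern, profile.p_r, profile.p_e1)
    if sm_mode == "mixture":
        q = (1.0 - beta) * q_base[None, :] + beta * p_e2_values[:, None]
    elif sm_mode == "subcell":
        if beta != 0.5:
            raise ValueError("subcell mode realizes a half-and-half split; beta must be 1/2")
        n = len(pattern)
        q = np.empty((p_e2_values.size, 2 * n))
        q[:, 0::2] = q_base[None, :]
        q[:, 1::2] = p_e2_values[:, None]
    else:
        raise ValueError(f"unknown sm_mode {sm_mode!r}")
    px = batch_nonlinear_px(q)
    alpha = pattern.alpha
    lin = beta * p_e2_values + (1.0 - beta) * (alpha * profile.p_r + (1.0 - alpha) * profile.p_e1)
    deriv = np.gradient(px, p_e2_values)
    return SensitivityCurve(
        p_e2_values=p_e2_values,
        p_x_values=px,
        p_x_linear_values=lin,
        derivative=deriv,
    )


def _sm_gain(p_e2: float, p_r: float, p_e1: float, beta: float, pattern: CellPattern,
             sm_mode: str, px_no: float) -> float:
    profile = DecisionProfile(p_r=p_r, p_e1=p_e1, p_e2=float(p_e2), beta=beta)
    chain = build_ring_chain(pattern, profile, use_sm=True, sm_mode=sm_mode)
    pi = stationary_distribution(chain)
    return nonlinear_predictive_ability(pi, chain) - px_no


def sm_advantage_boundary(
    p_r_values: np.ndarray,
    p_e1: float,
    beta: float,
    pattern: CellPattern,
    sm_mode: str = "mixture",
    scan_step: float = 1e-3,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Minimal ``p_e2`` at which markers beat the no-marker chain, per ``p_r``.

    A dense scan at ``scan_step`` certifies a single sign change of the
    gain ``p_x_with_sm - p_x_no_sm`` over [0, 1]; the crossing is then
    refined by bisection (Brent) to ``tol``.  Rows where the gain never
    changes sign report NaN with ``found = False``.
    """
    p_r_values = np.atleast_1d(np.asarray(p_r_values, dtype=float))
    grid = np.arange(0.0, 1.0 + scan_step / 2, scan_step)
    rows = []
    for p_r in p_r_values:
        q_no = _pattern_forward(pattern, p_r, p_e1)
        px_no = batch_nonlinear_px(q_no[None, :])[0]
        if sm_mode == "mixture":
            q = (1.0 - beta) * q_no[None, :] + beta * grid[:, None]
        else:
            n = len(pattern)
            q = np.empty((grid.size, 2 * n))
            q[:, 0::2] = q_no[None, :]
            q[:, 1::2] = grid[:, None]
        gain = batch_nonlinear_px(q) - px_no
        sign = np.sign(gain)
        finite = ~np.isnan(gain)
        crossings = np.flatnonzero((sign[:-1] < 0) & (sign[1:] >= 0) & finite[:-1] & finite[1:])
        n_cross = crossings.size
        if n_cross == 0:
            rows.append({"p_r": float(p_r), "boundary_p_e2": np.nan,
                         "found": False, "n_sign_changes": 0})
            continue
        lo, hi = grid[crossings[0]], grid[crossings[0] + 1]
        if gain[crossings[0] + 1] == 0.0:
            boundary = float(hi)
        else:
            boundary = float(
                brentq(_sm_gain, lo, hi, xtol=tol,
                       args=(float(p_r), p_e1, beta, pattern, sm_mode, px_no))
            )
        rows.append({"p_r": float(p_r), "boundary_p_e2": boundary,
                     "found": True, "n_sign_changes": int(n_cross)})
    return pd.DataFrame(rows)
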