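"""Seeded Monte-Carlo simulators for decision chains.

Three simulators cross-check and extend the analytic ring model:

- :func:`simulate_ring` — a single long trajectory on the cyclic chain,
  validating the analytic stationary occupancies;
- :func:`simulate_finite_road` — many runs on a finite road (reflecting
  start, absorbing goal), validating the effective forward-move fraction;
- :func:`simulate_grid_2d` — the two-dimensional extension, for which no
  analytic solution is available.  Per step the agent makes a correct move
  with the cell's forward probability (a uniform choice among neighbors
  that reduce lattice distance to the goal); otherwise it moves back,
  by default to the previously occupied cell.  A failure before any move
  leaves the agent in place.  Two alternative failure rules are available;
  see :func:`simulate_grid_2d`.

All randomness flows through ``numpy.random.Generator`` instances derived
from a user-supplied seed; identical seeds give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Cell, CellPattern, DecisionProfile, RingChain, forward_probability

__all__ = [
    "Grid2DEstimate",
    "GridWorld2D",
    "RingOccupancy",
    "SimulationConfig",
    "TrajectoryRecord",
    "boundary_curve_2d",
    "build_grid_world",
    "simulate_finite_road",
    "simulate_grid_2d",
    "simulate_ring",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Run-size and seeding parameters, echoed into every output."""

    seed: int
    steps: int | None = None
    runs: int | None = None
    max_steps_per_run: int = 100_000
    burn_in: int = 0

    def __post_init__(self) -> None:
        if self.steps is not None and self.steps < 1:
            raise ValueError("steps must be positive")
        if self.runs is not None and self.runs < 1:
            raise ValueError("runs must be positive")
        if self.max_steps_per_run < 1:
            raise ValueError("max_steps_per_run must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")


@dataclass(frozen=True, eq=False)
class TrajectoryRecord:
    """Bookkeeping for one trajectory.

    ``visit_counts`` includes the initial state, so it sums to
    ``steps_taken + 1``; ``forward_moves + backward_moves = steps_taken``
    (a blocked backward move at a reflecting start still counts as a
    backward move).
    """

    visit_counts: np.ndarray
    forward_moves: int
    backward_moves: int
    steps_taken: int
    reached_goal: bool | None = None

    def __post_init__(self) -> None:
        if self.forward_moves + self.backward_moves != self.steps_taken:
            raise ValueError("forward + backward moves must equal steps taken")
        if int(self.visit_counts.sum()) != self.steps_taken + 1:
            raise ValueError("visit counts must sum to steps_taken + 1")

    @property
    def forward_fraction(self) -> float:
        return self.forward_moves / self.steps_taken if self.steps_taken else float("nan")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectoryRecord):
            return NotImplemented
        return (
            self.forward_moves == other.forward_moves
            and self.backward_moves == other.backward_moves
            and self.steps_taken == other.steps_taken
            and self.reached_goal == other.reached_goal
            and np.array_equal(self.visit_counts, other.visit_counts)
        )


@dataclass(frozen=True, eq=False)
class RingOccupancy:
    """Ring-simulation result: full trajectory record plus post-burn-in occupancy."""

    record: TrajectoryRecord
    occupancy: np.ndarray
    config: SimulationConfig

    def __eq__(self, other) -> bool:
        if not isinstance(other, RingOccupancy):
            return NotImplemented
        return (
            self.record == other.record
            and self.config == other.config
            and np.array_equal(self.occupancy, other.occupancy)
        )


@dataclass(frozen=True)
class GridWorld2D:
    """Rectangular lattice of LIGHT/DARK cells with a start and a goal."""

    width: int
    height: int
    dark: np.ndarray  # (height, width) bool, True = DARK
    start: tuple[int, int]
    goal: tuple[int, int]

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must have positive area")
        if self.dark.shape != (self.height, self.width):
            raise ValueError("dark mask shape must be (height, width)")
        for name, (x, y) in (("start", self.start), ("goal", self.goal)):
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"{name} {x, y} outside the grid")
        if self.start == self.goal:
            raise ValueError("start and goal must differ")

    @property
    def dark_fraction(self) -> float:
        return float(self.dark.mean())


@dataclass(frozen=True)
class Grid2DEstimate:
    """Pooled correct-move fraction over all steps of all runs, with its
    ratio-estimator standard error (runs as independent clusters)."""

    p_correct: float
    se: float
    runs: int
    total_moves: int
    goal_rate: float
    mean_steps: float
    config: SimulationConfig = field(repr=False)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def simulate_ring(chain: RingChain, config: SimulationConfig) -> RingOccupancy:
    """Walk a single trajectory of ``config.steps`` steps on the ring.

    The returned ``occupancy`` is the empirical visit frequency over the
    states visited after ``config.burn_in`` steps.
    """
    if config.steps is None:
        raise ValueError("simulate_ring requires config.steps")
    steps, burn = config.steps, config.burn_in
    if burn >= steps:
        raise ValueError("burn_in must be smaller than steps")
    q = chain.forward_prob
    n = chain.size
    rng = _rng(config.seed)
    u = rng.random(steps)
    states = np.empty(steps + 1, dtype=np.int64)
    state = 0
    states[0] = state
    for t in range(steps):
        if u[t] < q[state]:
            state = state + 1 if state + 1 < n else 0
        else:
            state = state - 1 if state > 0 else n - 1
        states[t + 1] = state
    fwd = int(((states[1:] - states[:-1]) % n == 1).sum())
    record = TrajectoryRecord(
        visit_counts=np.bincount(states, minlength=n),
        forward_moves=fwd,
        backward_moves=steps - fwd,
        steps_taken=steps,
        reached_goal=None,
    )
    post = np.bincount(states[burn + 1 :], minlength=n).astype(float)
    return RingOccupancy(record=record, occupancy=post / post.sum(), config=config)


def _road_forward_probs(
    pattern: CellPattern,
    length: int,
    profile: DecisionProfile,
    use_sm: bool,
) -> np.ndarray:
    cells = [pattern.cells[i % len(pattern)] for i in range(length)]
    return np.array([forward_probability(c, profile, use_sm) for c in cells])


def simulate_finite_road(
    pattern: CellPattern,
    length: int,
    profile: DecisionProfile,
    use_sm: bool,
    config: SimulationConfig,
) -> list[TrajectoryRecord]:
    """Many independent runs on a finite road of ``length`` cells.

    The pattern repeats along the road; position 0 reflects (a retreat
    leaves the agent in place but is counted as a backward move) and the
    goal at position ``length`` absorbs.  Run ``k`` draws from its own
    child generator seeded by ``(seed, k)``, so any single run is
    reproducible in isolation.
    """
    if length < 3:
        raise ValueError("road length must be at least 3")
    if config.runs is None:
        raise ValueError("simulate_finite_road requires config.runs")
    q = _road_forward_probs(pattern, length, profile, use_sm)
    records = []
    cap = config.max_steps_per_run
    for k in range(config.runs):
        rng = _rng(config.seed, k)
        pos = 0
        counts = np.zeros(length + 1, dtype=np.int64)
        counts[0] = 1
        fwd = steps = 0
        reached = False
        while steps < cap:
            if rng.random() < q[pos]:
                pos += 1
                fwd += 1
            elif pos > 0:
                pos -= 1
            steps += 1
            counts[pos] += 1
            if pos == length:
                reached = True
                break
        records.append(
            TrajectoryRecord(
                visit_counts=counts,
                forward_moves=fwd,
                backward_moves=steps - fwd,
                steps_taken=steps,
                reached_goal=reached,
            )
        )
    return records


def build_grid_world(
    width: int,
    height: int,
    dark_fraction: float,
    layout_mode: str = "striped",
    seed: int | None = None,
    start: tuple[int, int] | None = None,
    goal: tuple[int, int] | None = None,
) -> GridWorld2D:
    """Lay out a 2D world of LIGHT/DARK cells.

    ``layout_mode="striped"`` darkens every k-th column (k = round(1 /
    dark_fraction)), mirroring the 1D repeating pattern.  The dark stripe
    sits mid-period (column index k // 2 within each period) so that for
    the default corner start and goal neither endpoint falls inside a
    dark stripe: an absorbing goal inside a dark column would force a
    consecutive run of dark decisions that has no counterpart in the 1D
    road, where dark cells are always crossed singly.  ``"random"``
    darkens each cell independently with probability ``dark_fraction``
    (requires ``seed``).
    """
    if not (0.0 <= dark_fraction <= 1.0):
        raise ValueError("dark_fraction must lie in [0, 1]")
    if width < 1 or height < 1:
        raise ValueError("grid must have positive area")
    if layout_mode == "striped":
        if dark_fraction == 0.0:
            dark = np.zeros((height, width), dtype=bool)
        else:
            k = max(1, round(1.0 / dark_fraction))
            cols = (np.arange(width) % k) == k // 2 if k > 1 else np.ones(width, dtype=bool)
            dark = np.tile(cols, (height, 1))
    elif layout_mode == "random":
        if seed is None:
            raise ValueError("random layout requires a seed")
        dark = _rng(seed).random((height, width)) < dark_fraction
    else:
        raise ValueError(f"unknown layout_mode {layout_mode!r}")
    return GridWorld2D(
        width=width,
        height=height,
        dark=dark,
        start=start if start is not None else (0, 0),
        goal=goal if goal is not None else (width - 1, height - 1),
    )


def _q_grid(world: GridWorld2D, profile: DecisionProfile, use_sm: bool) -> np.ndarray:
    q_light = forward_probability(Cell.LIGHT, profile, use_sm)
    q_dark = forward_probability(Cell.DARK, profile, use_sm)
    return np.where(world.dark, q_dark, q_light)


_DIRS = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)])


def _worsening_neighbor(ax, ay, dx, dy, world: GridWorld2D, rng: np.random.Generator):
    """Uniformly pick an in-bounds neighbor that does not reduce goal distance.

    On a 4-neighborhood every neighbor strictly changes the Manhattan
    distance, so "non-improving" and "distance-increasing" coincide.
    Returns (wx, wy, ok); ``ok`` is False where no such neighbor exists
    (then the caller leaves the agent in place).
    """
    m = ax.size
    cx = ax[None, :] + _DIRS[:, 0:1]
    cy = ay[None, :] + _DIRS[:, 1:2]
    in_bounds = (cx >= 0) & (cx < world.width) & (cy >= 0) & (cy < world.height)
    improving = ((_DIRS[:, 0:1] == dx[None, :]) & (_DIRS[:, 0:1] != 0)) | (
        (_DIRS[:, 1:2] == dy[None, :]) & (_DIRS[:, 1:2] != 0)
    )
    valid = in_bounds & ~improving
    count = valid.sum(axis=0)
    ok = count > 0
    pick = np.minimum((rng.random(m) * np.maximum(count, 1)).astype(np.int64), np.maximum(count - 1, 0))
    order = np.cumsum(valid, axis=0) - 1
    chosen = valid & (order == pick[None, :])
    which = chosen.argmax(axis=0)
    return cx[which, np.arange(m)], cy[which, np.arange(m)], ok


def simulate_grid_2d(
    world: GridWorld2D,
    profile: DecisionProfile,
    use_sm: bool,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    move_mode: str = "retreat",
) -> Grid2DEstimate:
    """Estimate the effective 2D predictive ability by Monte Carlo.

    All runs advance in lock-step (vectorized); per step an active agent
    succeeds with its cell's forward probability and moves to a uniformly
    chosen lattice-distance-reducing neighbor.  Failures follow
    ``move_mode``:

    - ``"retreat"`` (default): the agent returns to the previously
      occupied cell (a failure before any move leaves it in place).  In
      one dimension this reads "go back to the previous position"
      temporally: after a retreat i -> i-1, a second failure returns to i.
    - ``"away"``: the agent steps to a uniformly chosen in-bounds
      distance-*increasing* neighbor (staying put when none exists, e.g.
      at the corner opposite the goal).  This is the spatial reading of
      the 1D back-transition and reduces exactly to the finite road on a
      1-row world.
    - ``"wrong-move"``: a failure goes half the time to a uniformly
      chosen in-bounds non-improving neighbor and half the time back to
      the previously occupied cell; provided for sensitivity analysis.

    The two readings of "move back" coincide along an unbroken forward
    march and differ only after a retreat; the default follows the
    agent-centric (temporal) reading.  The estimate is the fraction of
    correct moves pooled over every step of every run; runs still active
    after ``max_steps_per_run`` steps are truncated and counted as not
    reaching the goal.
    """
    if config.runs is None:
        raise ValueError("simulate_grid_2d requires config.runs")
    if move_mode not in ("retreat", "away", "wrong-move"):
        raise ValueError(f"unknown move_mode {move_mode!r}")
    if rng is None:
        rng = _rng(config.seed)
    runs = config.runs
    qg = _q_grid(world, profile, use_sm)
    gx, gy = world.goal
    x = np.full(runs, world.start[0])
    y = np.full(runs, world.start[1])
    px = np.empty(runs, dtype=np.int64)  # previous cell; valid where has_prev
    py = np.empty(runs, dtype=np.int64)
    has_prev = np.zeros(runs, dtype=bool)
    active = np.ones(runs, dtype=bool)
    correct = np.zeros(runs, dtype=np.int64)
    moves = np.zeros(runs, dtype=np.int64)
    steps_done = np.zeros(runs, dtype=np.int64)
    reached = np.zeros(runs, dtype=bool)
    for _ in range(config.max_steps_per_run):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        ax, ay = x[idx], y[idx]
        q = qg[ay, ax]
        u = rng.random(idx.size)
        success = u < q
        dx = np.sign(gx - ax)
        dy = np.sign(gy - ay)
        both = (dx != 0) & (dy != 0)
        pick_x = dx != 0
        if both.any():
            # two improving neighbors: choose the axis uniformly
            pick_x = np.where(both, rng.random(idx.size) < 0.5, pick_x)
        nx = np.where(pick_x, ax + dx, ax)
        ny = np.where(pick_x, ay, ay + dy)
        fail = ~success
        if move_mode == "retreat":
            undo = fail & has_prev[idx]
            new_x = np.where(success, nx, np.where(undo, px[idx], ax))
            new_y = np.where(success, ny, np.where(undo, py[idx], ay))
            moved = success | undo
        elif move_mode == "away":
            wx, wy, ok = _worsening_neighbor(ax, ay, dx, dy, world, rng)
            back = fail & ok
            new_x = np.where(success, nx, np.where(back, wx, ax))
            new_y = np.where(success, ny, np.where(back, wy, ay))
            moved = success | back
        else:  # wrong-move: scatter half the time, undo the last move otherwise
            scatter = fail & (rng.random(idx.size) < 0.5)
            wx, wy, ok = _worsening_neighbor(ax, ay, dx, dy, world, rng)
            scatter &= ok
            undo = fail & ~scatter & has_prev[idx]
            new_x = np.where(success, nx, np.where(scatter, wx, np.where(undo, px[idx], ax)))
            new_y = np.where(success, ny, np.where(scatter, wy, np.where(undo, py[idx], ay)))
            moved = success | scatter | undo
        px[idx] = np.where(moved, ax, px[idx])
        py[idx] = np.where(moved, ay, py[idx])
        has_prev[idx] |= moved
        x[idx], y[idx] = new_x, new_y
        correct[idx] += success
        moves[idx] += 1
        steps_done[idx] += 1
        at_goal = (new_x == gx) & (new_y == gy)
        reached[idx] |= at_goal
        active[idx] = ~at_goal
    total_moves = int(moves.sum())
    est = float(correct.sum() / total_moves)
    resid = correct - est * moves
    se = float(np.sqrt((resid**2).sum() * runs / max(runs - 1, 1)) / total_moves)
    return Grid2DEstimate(
        p_correct=est,
        se=se,
        runs=runs,
        total_moves=total_moves,
        goal_rate=float(reached.mean()),
        mean_steps=float(steps_done.mean()),
        config=config,
    )


def boundary_curve_2d(
    p_r_values: np.ndarray,
    p_e1: float,
    beta: float,
    world: GridWorld2D,
    config: SimulationConfig,
    p_e2_range: tuple[float, float] = (0.0, 1.0),
    step: float = 0.025,
    move_mode: str = "retreat",
) -> pd.DataFrame:
    """Locate the 2D marker-advantage boundary in ``p_e2``, per ``p_r``.

    For each ``p_r`` the no-marker ability is estimated once, then the
    marker ability is scanned over ``p_e2`` at ``step``; the boundary is
    the linear interpolation of the first crossing of the gain through
    zero, with a standard error propagated from the two bracketing
    estimates through the local slope.  Scans whose gain changes sign more
    than once (at the given noise level) are flagged ``uncertain``.

    Each simulation draws from a child generator sub-seeded by a fixed
    offset, so any (p_r, p_e2) point is reproducible in isolation.
    """
    p_r_values = np.atleast_1d(np.asarray(p_r_values, dtype=float))
    lo, hi = p_e2_range
    grid = np.arange(lo, hi + step / 2, step)
    rows = []
    for i, p_r in enumerate(p_r_values):
        base_profile = DecisionProfile(p_r=float(p_r), p_e1=p_e1)
        base = simulate_grid_2d(
            world, base_profile, False, config, rng=_rng(config.seed, i, 0), move_mode=move_mode
        )
        gains = np.empty(grid.size)
        ses = np.empty(grid.size)
        for j, p_e2 in enumerate(grid):
            prof = DecisionProfile(p_r=float(p_r), p_e1=p_e1, p_e2=float(p_e2), beta=beta)
            est = simulate_grid_2d(
                world, prof, True, config, rng=_rng(config.seed, i, j + 1), move_mode=move_mode
            )
            gains[j] = est.p_correct - base.p_correct
            ses[j] = float(np.hypot(est.se, base.se))
        sign = np.sign(gains)
        cross = np.flatnonzero((sign[:-1] < 0) & (sign[1:] >= 0))
        n_cross = cross.size
        if n_cross == 0:
            rows.append({"p_r": float(p_r), "boundary_p_e2": np.nan, "se": np.nan,
                         "found": False, "uncertain": True})
            continue
        j = cross[0]
        slope = (gains[j + 1] - gains[j]) / step
        boundary = grid[j] - gains[j] / slope
        se_b = float(np.hypot(ses[j], ses[j + 1]) / abs(slope)) if slope != 0 else np.nan
        rows.append({"p_r": float(p_r), "boundary_p_e2": float(boundary), "se": se_b,
                     "found": True, "uncertain": bool(n_cross > 1)})
    return pd.DataFrame(rows)
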