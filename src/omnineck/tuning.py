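"""Gain tuning: curve-mapping objective, saturation-penalized activity
constraint, and sequential response-surface optimization with domain
reduction (SRSM).

The optimizer fits a linear metamodel to a handful of simulations per
iteration (7, D-optimal selection from a Latin-hypercube candidate pool),
minimizes the scalarized metamodel objective inside the current trust
region subject to the activity constraint, then pans the region to the
predicted optimum and zooms its ranges.  This mirrors the metamodel-based
tuning workflow used for active human body model controllers, scaled to a
desk-size surrogate plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.stats import qmc

from .controller import REFERENCE_CONTROLLERS, ControllerGains, ReferenceController
from .plant import SimulationResult

__all__ = [
    "GainBounds",
    "DesignSpace",
    "TuningProblem",
    "IterationRecord",
    "TuningResult",
    "InfeasibleStartError",
    "UndefinedNormalizationError",
    "curve_mapping_distance",
    "rms_distance",
    "saturation_penalized_activity",
    "ki_ceiling_from_references",
    "srsm_optimize",
]


class InfeasibleStartError(RuntimeError):
    """No feasible design in the first iteration: the starting values must
    lie in a region where the activity constraint can be met."""


class UndefinedNormalizationError(ValueError):
    """Curve comparison against an identically-zero reference is undefined."""


@dataclass(frozen=True)
class GainBounds:
    start: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum <= self.start <= self.maximum:
            raise ValueError("bounds require minimum <= start <= maximum")


def ki_ceiling_from_references(
    references: Sequence[ReferenceController] = REFERENCE_CONTROLLERS,
) -> float:
    """Upper tuning bound for Ki: the largest theoretical Ziegler-Nichols
    Ki across the published reference controllers, rounded up to the
    nearest order of magnitude."""
    top = max(r.theoretical_ki for r in references)
    return 10.0 ** math.ceil(math.log10(top))


@dataclass(frozen=True)
class DesignSpace:
    """Start/min/max per gain; defaults follow the published tuning setup
    (Kp 0.1 in [0, 2]; Ki 1e-6 in [0, 0.1]; Kd 100 in [0, 1000]), with the
    Ki ceiling derivable from :func:`ki_ceiling_from_references`."""

    kp: GainBounds = GainBounds(0.1, 0.0, 2.0)
    ki: GainBounds = GainBounds(1e-6, 0.0, 0.1)
    kd: GainBounds = GainBounds(100.0, 0.0, 1000.0)

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.kp.minimum, self.ki.minimum, self.kd.minimum])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.kp.maximum, self.ki.maximum, self.kd.maximum])

    @property
    def start(self) -> np.ndarray:
        return np.array([self.kp.start, self.ki.start, self.kd.start])


@dataclass(frozen=True)
class TuningProblem:
    """What the tuner minimizes: named load cases with objective channels,
    an objective set (T, R or TR), the activity ceiling, and scalarization
    weights (equal by default)."""

    load_cases: tuple[tuple[str, tuple[str, ...]], ...]
    objective_set: str = "TR"
    constraint_ceiling: float = 0.99
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.objective_set not in ("T", "R", "TR"):
            raise ValueError("objective set must be T, R or TR")
        n_obj = sum(len(ch) for _, ch in self.load_cases)
        if n_obj not in (2, 4):
            raise ValueError("tuning uses two or four objectives")
        if self.weights is not None and len(self.weights) != n_obj:
            raise ValueError("one weight per objective required")


def curve_mapping_distance(
    sim: np.ndarray, ref: np.ndarray, time: np.ndarray, n_points: int = 200
) -> float:
    """Curve-mapping discrepancy between two time series on a common base.

    Both curves are normalized by the reference peak magnitude (y) and the
    common duration (t), traced as polylines in the normalized (t, y)
    plane, re-sampled at ``n_points`` equal fractions of their own arc
    length, and compared point-by-point; the result is the mean Euclidean
    offset along the mapped arc.  Zero iff the curves are identical.  The
    normalization is anchored on the reference, so the metric is *not*
    symmetric in its arguments.
    """
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    time = np.asarray(time, dtype=float)
    if sim.shape != ref.shape or sim.shape != time.shape:
        raise ValueError("series must share the common time base")
    peak = np.max(np.abs(ref))
    if peak <= 0.0:
        raise UndefinedNormalizationError("reference curve is identically zero")
    duration = time[-1] - time[0]
    if duration <= 0.0:
        raise ValueError("time base must span a positive duration")

    t_n = (time - time[0]) / duration

    def arc_resample(y: np.ndarray) -> np.ndarray:
        pts = np.column_stack([t_n, y / peak])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= 0.0:
            total = 1.0
        grid = np.linspace(0.0, s[-1], n_points)
        return np.column_stack(
            [np.interp(grid, s, pts[:, 0]), np.interp(grid, s, pts[:, 1])]
        )

    a = arc_resample(sim)
    b = arc_resample(ref)
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def rms_distance(sim: np.ndarray, ref: np.ndarray, time: np.ndarray) -> float:
    """Plain RMS-after-resampling alternative metric for sensitivity checks."""
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    peak = np.max(np.abs(ref))
    if peak <= 0.0:
        raise UndefinedNormalizationError("reference curve is identically zero")
    return float(np.sqrt(np.mean((sim - ref) ** 2)) / peak)


def saturation_penalized_activity(
    result: SimulationResult,
    ceiling: float = 0.99,
    duration_scale: float = 1.0,
    signal: str = "pid",
) -> float:
    """Constraint response: maximum activity, penalized by saturation time.

    Below the ceiling the response is just the maximum activity.  At or
    above it, the total saturated duration (seconds, scaled by
    ``duration_scale``) is added, so the optimizer can order otherwise
    indistinguishable saturated designs by how long they stayed saturated.
    The constrained signal is the saturating PID response by default
    (``signal="activation"`` switches to the post-dynamics Na).
    """
    if signal == "pid":
        peak = float(np.clip(result.pid_response, 0.0, 1.0).max(initial=0.0))
        sat_s = result.saturated_ms / 1000.0
    elif signal == "activation":
        peak = float(result.activations.max(initial=0.0))
        dt = float(result.time[1] - result.time[0]) if len(result.time) > 1 else 0.0
        sat_s = float((result.activations.max(axis=1) >= 1.0).sum()) * dt
    else:
        raise ValueError("signal must be 'pid' or 'activation'")
    if peak < ceiling:
        return peak
    return ceiling + duration_scale * sat_s


@dataclass
class IterationRecord:
    index: int
    center: np.ndarray
    ranges: np.ndarray
    designs: np.ndarray  # (7, 3)
    objectives: np.ndarray  # (7, n_obj)
    constraints: np.ndarray  # (7,)
    coefficients: np.ndarray  # linear metamodel of the scalarized objective
    predicted_optimum: np.ndarray


@dataclass
class TuningResult:
    gains: ControllerGains
    objective: float
    constraint: float
    constraint_violated: bool
    history: list[IterationRecord] = field(default_factory=list)
    termination: str = ""


def _d_optimal_select(
    candidates: np.ndarray, n_select: int, forced: np.ndarray | None
) -> np.ndarray:
    """Greedy D-optimal subset for a linear model with intercept."""

    def model_row(x: np.ndarray) -> np.ndarray:
        return np.concatenate([[1.0], x])

    selected: list[np.ndarray] = [] if forced is None else [f for f in forced]
    chosen_idx: set[int] = set()
    while len(selected) < n_select:
        best_det, best_j = -np.inf, None
        for j in range(len(candidates)):
            if j in chosen_idx:
                continue
            rows = np.array([model_row(x) for x in selected + [candidates[j]]])
            m = rows.T @ rows + 1e-12 * np.eye(rows.shape[1])
            sign, logdet = np.linalg.slogdet(m)
            score = logdet if sign > 0 else -np.inf
            if score > best_det:
                best_det, best_j = score, j
        chosen_idx.add(best_j)
        selected.append(candidates[best_j])
    return np.array(selected)


def srsm_optimize(
    problem: TuningProblem,
    space: DesignSpace,
    simulator: Callable[[ControllerGains], tuple[np.ndarray, float]],
    seed: int,
    *,
    n_designs: int = 7,
    max_iterations: int = 10,
    tolerance: float = 0.01,
    zoom: float = 0.6,
    pool_size: int = 200,
) -> TuningResult:
    """Sequential response-surface gain optimization with domain reduction.

    Per iteration: draw a Latin-hypercube candidate pool inside the current
    region, pick ``n_designs`` designs by greedy D-optimal selection (the
    starting design is forced into iteration 1), evaluate the simulator,
    fit linear metamodels for the scalarized objective and the constraint,
    minimize the metamodel objective over the region subject to
    ``constraint <= ceiling`` (a linear program), then pan the region
    centre to the predicted optimum and zoom the ranges by ``zoom``.
    Terminates when the relative design change and objective change both
    drop below ``tolerance``, or after ``max_iterations``.  The reported
    design is the best *simulated* feasible one; if every simulated design
    violates the constraint the result is flagged.

    ``simulator`` maps gains to (objective vector, constraint response).
    Deterministic for a given seed (the candidate pool is the only
    stochastic element).
    """
    rng = np.random.default_rng(seed)
    lo, hi = space.lower, space.upper
    span = hi - lo
    center = space.start.astype(float).copy()
    ranges = span / 2.0

    n_obj = sum(len(ch) for _, ch in problem.load_cases)
    weights = (
        np.asarray(problem.weights, dtype=float)
        if problem.weights is not None
        else np.full(n_obj, 1.0 / n_obj)
    )
    ceiling = problem.constraint_ceiling

    best: tuple[float, np.ndarray, float] | None = None  # (objective, x, constraint)
    best_any: tuple[float, np.ndarray, float] | None = None
    history: list[IterationRecord] = []
    prev_center, prev_obj = None, None
    termination = f"max iterations ({max_iterations})"

    for it in range(1, max_iterations + 1):
        box_lo = np.maximum(lo, center - ranges)
        box_hi = np.minimum(hi, center + ranges)
        width = np.maximum(box_hi - box_lo, 1e-15)

        sampler = qmc.LatinHypercube(d=3, seed=rng)
        pool = box_lo + sampler.random(pool_size) * width
        pool_unit = (pool - box_lo) / width

        forced = None
        if it == 1:
            forced = ((space.start - box_lo) / width)[np.newaxis, :]
        unit_designs = _d_optimal_select(pool_unit, n_designs, forced)
        designs = box_lo + unit_designs * width

        objectives = np.zeros((n_designs, n_obj))
        constraints = np.zeros(n_designs)
        for i, x in enumerate(designs):
            obj, con = simulator(ControllerGains(*x))
            objectives[i] = np.asarray(obj, dtype=float)
            constraints[i] = con
            f = float(weights @ objectives[i])
            if con <= ceiling and (best is None or f < best[0]):
                best = (f, x.copy(), con)
            if best_any is None or f < best_any[0]:
                best_any = (f, x.copy(), con)

        if it == 1 and best is None:
            raise InfeasibleStartError(
                "no feasible design in the first iteration; move the starting "
                "values toward a region with activity below the constraint"
            )

        # Linear metamodels in unit region coordinates.
        x_mat = np.column_stack([np.ones(n_designs), unit_designs])
        f_scalar = objectives @ weights
        coef_obj, *_ = np.linalg.lstsq(x_mat, f_scalar, rcond=None)
        coef_con, *_ = np.linalg.lstsq(x_mat, constraints, rcond=None)

        res = linprog(
            c=coef_obj[1:],
            A_ub=coef_con[1:][np.newaxis, :],
            b_ub=[ceiling - coef_con[0]],
            bounds=[(0.0, 1.0)] * 3,
            method="highs",
        )
        if res.success:
            x_unit_opt = res.x
        else:  # metamodel constraint infeasible everywhere: minimize it instead
            res2 = linprog(
                c=coef_con[1:], bounds=[(0.0, 1.0)] * 3, method="highs"
            )
            x_unit_opt = res2.x
        x_opt = box_lo + x_unit_opt * width
        f_pred = float(coef_obj[0] + coef_obj[1:] @ x_unit_opt)

        history.append(
            IterationRecord(
                index=it,
                center=center.copy(),
                ranges=ranges.copy(),
                designs=designs,
                objectives=objectives,
                constraints=constraints,
                coefficients=coef_obj,
                predicted_optimum=x_opt,
            )
        )

        new_center = np.clip(x_opt, lo, hi)
        design_change = float(np.max(np.abs(new_center - center) / span))
        obj_change = (
            abs(f_pred - prev_obj) / max(abs(prev_obj), 1e-12)
            if prev_obj is not None
            else np.inf
        )
        prev_center, prev_obj = center, f_pred
        center = new_center
        ranges = ranges * zoom

        if design_change < tolerance and obj_change < tolerance:
            termination = f"converged at iteration {it}"
            break

    chosen = best if best is not None else best_any
    f_best, x_best, con_best = chosen
    return TuningResult(
        gains=ControllerGains(*x_best),
        objective=f_best,
        constraint=con_best,
        constraint_violated=con_best > ceiling,
        history=history,
        termination=termination,
    )
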