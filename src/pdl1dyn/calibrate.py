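"""Bound-constrained least-squares calibration of the ϵ parameters.

Two fitting modes mirror the two model variants: a scalar PD-L1
propensity ϵ fitted independently per therapy arm (base model, k=1 per
arm), and the five parameters of the dynamic ϵ equation fitted jointly
across all six arms by pooling residuals (k=5).  The loss is the plain
unweighted sum of squared errors on tumor volumes.  Local minima are
mitigated by seeded Latin-hypercube multi-starts; among starts whose
final cost ties within tolerance, the most parsimonious (smallest-norm)
parameter vector is reported so that arms carrying no information about
ϵ yield the minimal propensity consistent with the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import ModelVariant
from .params import BaseParams, EpsilonParams
from .simulate import Trajectory, TreatmentSchedule, integrate, standard_arms

__all__ = ["TherapyDataset", "FitResult", "residuals", "fit_constant_eps", "fit_dynamic_eps"]

#: relative cost tolerance under which two multi-start optima are tied
_TIE_RTOL = 1e-6


@dataclass
class TherapyDataset:
    """Observed (day, tumor volume mm³) pairs for one therapy arm.

    ``include`` is an explicit per-point mask; excluded points (e.g.
    flagged outliers) are kept in the container but never residualized.
    """

    therapy_id: str
    days: np.ndarray
    volumes: np.ndarray
    include: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.shape != self.volumes.shape or self.days.ndim != 1:
            raise ValueError("days and volumes must be 1-D arrays of equal length")
        if np.any(np.diff(self.days) < 0):
            raise ValueError("days must be nondecreasing")
        if len(np.unique(self.days)) != len(self.days):
            raise ValueError("one record per (therapy, day): duplicate days found")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be strictly positive")
        if self.include is None:
            self.include = np.ones(self.days.shape, dtype=bool)
        else:
            self.include = np.asarray(self.include, dtype=bool)
            if self.include.shape != self.days.shape:
                raise ValueError("include mask must match days")

    @property
    def n(self) -> int:
        """Number of observations that enter the residual vector."""
        return int(self.include.sum())

    @property
    def observed_days(self) -> np.ndarray:
        return self.days[self.include]

    @property
    def observed_volumes(self) -> np.ndarray:
        return self.volumes[self.include]


@dataclass
class FitResult:
    """Outcome of a calibration run.

    ``params`` maps parameter names to estimates (``{"eps": ...}`` for
    the constant fit; the five ϵ-equation fields for the dynamic fit).
    ``per_therapy_rss`` and ``n_per_therapy`` are keyed by therapy id;
    ``k`` is the free-parameter count used downstream in AIC.
    """

    variant: ModelVariant
    params: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    per_therapy_rss: dict[str, float]
    n_per_therapy: dict[str, int]
    k: int
    converged: bool
    n_restarts: int
    seed: int | None
    message: str = ""

    @property
    def total_rss(self) -> float:
        return float(sum(self.per_therapy_rss.values()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variant"] = self.variant.value
        d["total_rss"] = self.total_rss
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def residuals(traj: Trajectory, data: TherapyDataset, scale: str = "volume") -> np.ndarray:
    """Model-minus-observed tumor volumes at the included observation days.

    Model values are interpolated on the trajectory's dense grid; an
    observation outside the trajectory's time span is a domain error.
    With ``scale="log"`` residuals are taken on log volumes (useful when
    arms span orders of magnitude); the default is plain volumes.
    """
    model_v = traj.volume_at(data.observed_days)
    if scale == "log":
        floor = np.finfo(float).tiny
        return np.log(np.maximum(model_v, floor)) - np.log(data.observed_volumes)
    if scale != "volume":
        raise ValueError(f"scale must be 'volume' or 'log', got {scale!r}")
    return model_v - data.observed_volumes


def _multistart_lhs(bounds_lo, bounds_hi, restarts, seed) -> np.ndarray:
    d = len(bounds_lo)
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    unit = sampler.random(restarts)
    return qmc.scale(unit, bounds_lo, bounds_hi)


class _Solution:
    """Minimal result carrier for the fully-fixed-bounds degenerate case."""

    def __init__(self, x, cost):
        self.x, self.cost = x, cost


def _run_multistart(objective, bounds_lo, bounds_hi, restarts, seed):
    """Least-squares from LHS starts; returns (best, n_ok, message).

    Parameters whose lower and upper bounds coincide are held fixed at
    that value rather than optimized.
    """
    bounds_lo = np.asarray(bounds_lo, dtype=float)
    bounds_hi = np.asarray(bounds_hi, dtype=float)
    free = bounds_hi > bounds_lo
    if not free.any():
        x = bounds_lo.copy()
        r = objective(x)
        return _Solution(x, 0.5 * float(np.sum(r**2))), 1, ""

    def embed(x_free):
        x = bounds_lo.copy()
        x[free] = x_free
        return x

    starts = _multistart_lhs(bounds_lo[free], bounds_hi[free], restarts, seed)
    best = None
    failures: list[str] = []
    for x0 in starts:
        try:
            sol = least_squares(
                lambda xf: objective(embed(xf)),
                x0,
                bounds=(bounds_lo[free], bounds_hi[free]),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                # keep finite-difference steps above the integrator noise floor
                diff_step=1e-4,
            )
        except Exception as exc:  # integrator blow-up on a pathological start
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        sol = _Solution(embed(sol.x), sol.cost)
        if best is None:
            best = sol
        else:
            tol = _TIE_RTOL * max(best.cost, 1.0) + 1e-300
            if sol.cost < best.cost - tol:
                best = sol
            elif abs(sol.cost - best.cost) <= tol and np.linalg.norm(sol.x) < np.linalg.norm(best.x):
                best = sol  # parsimony tie-break
    n_ok = len(starts) - len(failures)
    message = "; ".join(sorted(set(failures))) if failures else ""
    return best, n_ok, message


def _resolve_schedule(data: TherapyDataset, schedule: TreatmentSchedule | None):
    if schedule is not None:
        return schedule
    arms = standard_arms()
    if data.therapy_id not in arms:
        raise KeyError(
            f"no schedule given and therapy {data.therapy_id!r} is not a standard arm"
        )
    return arms[data.therapy_id]


def fit_constant_eps(
    data: TherapyDataset,
    p: BaseParams,
    schedule: TreatmentSchedule | None = None,
    bounds: tuple[float, float] = (0.0, 5000.0),
    restarts: int = 20,
    seed: int | None = None,
    rtol: float = 1e-6,
    atol: float | None = None,
    V0: float = 100.0,
    loss: str = "volume",
) -> FitResult:
    """Fit the scalar PD-L1 propensity ϵ of the base model to one arm.

    ``loss`` selects the residual scale ("volume" by default, "log" as
    an option); the reported RSS is on the fitted scale.
    """
    if data.n == 0:
        raise ValueError(f"dataset for therapy {data.therapy_id!r} has no included observations")
    schedule = _resolve_schedule(data, schedule)
    horizon = float(max(data.observed_days.max(), max(schedule.dose_times(), default=0.0)))
    horizon = max(horizon, 1e-6)
    obs_days = data.observed_days

    def objective(x):
        traj = integrate(
            p,
            schedule,
            variant=ModelVariant.CONSTANT,
            eps=float(x[0]),
            V0=V0,
            horizon=horizon,
            t_eval=obs_days,
            rtol=rtol,
            atol=atol,
        )
        return residuals(traj, data, scale=loss)

    best, n_ok, message = _run_multistart(
        objective, np.array([bounds[0]]), np.array([bounds[1]]), restarts, seed
    )
    if best is None:
        return FitResult(
            variant=ModelVariant.CONSTANT,
            params={},
            bounds={"eps": bounds},
            per_therapy_rss={},
            n_per_therapy={data.therapy_id: data.n},
            k=1,
            converged=False,
            n_restarts=restarts,
            seed=seed,
            message=f"no restart converged: {message}",
        )
    rss = float(2.0 * best.cost)
    return FitResult(
        variant=ModelVariant.CONSTANT,
        params={"eps": float(best.x[0])},
        bounds={"eps": bounds},
        per_therapy_rss={data.therapy_id: rss},
        n_per_therapy={data.therapy_id: data.n},
        k=1,
        converged=True,
        n_restarts=restarts,
        seed=seed,
        message=message,
    )


_EPS_FIELDS = ("k_basal", "K_V", "alpha_A1", "alpha_A2", "d_eps")


def default_dynamic_bounds(scale: float = 10.0) -> dict[str, tuple[float, float]]:
    """Nonnegative box bounds, upper bound ``scale``× the default values."""
    ref = EpsilonParams()
    return {name: (0.0, scale * getattr(ref, name)) for name in _EPS_FIELDS}


def fit_dynamic_eps(
    datasets: Mapping[str, TherapyDataset] | Sequence[TherapyDataset],
    p: BaseParams,
    schedules: Mapping[str, TreatmentSchedule] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    restarts: int = 20,
    seed: int | None = None,
    rtol: float = 1e-6,
    atol: float | None = None,
    V0: float = 100.0,
    loss: str = "volume",
) -> FitResult:
    """Jointly fit the five ϵ-equation parameters across all six arms.

    Residual vectors of the arms are concatenated so the pooled SSE is
    minimized; per-arm RSS (on the fitted ``loss`` scale) are reported
    alongside the estimates.
    """
    if not isinstance(datasets, Mapping):
        datasets = {d.therapy_id: d for d in datasets}
    if schedules is None:
        schedules = standard_arms()
    missing = sorted(set(schedules) - set(datasets))
    if missing:
        raise ValueError(f"missing therapy arm(s): {missing}")
    for tid, data in datasets.items():
        if data.n == 0:
            raise ValueError(f"dataset for therapy {tid!r} has no included observations")
    if bounds is None:
        bounds = default_dynamic_bounds()
    lo = np.array([bounds[name][0] for name in _EPS_FIELDS], dtype=float)
    hi = np.array([bounds[name][1] for name in _EPS_FIELDS], dtype=float)

    order = sorted(schedules)
    horizons = {
        tid: max(
            float(datasets[tid].observed_days.max()),
            max(schedules[tid].dose_times(), default=0.0),
            1e-6,
        )
        for tid in order
    }

    def arm_residuals(tid, x):
        vals = dict(zip(_EPS_FIELDS, np.maximum(x, 0.0)))
        vals["K_V"] = max(vals["K_V"], 1e-12)  # K_V must stay positive
        q = EpsilonParams(**vals)
        traj = integrate(
            p,
            schedules[tid],
            variant=ModelVariant.DYNAMIC,
            eps_params=q,
            V0=V0,
            horizon=horizons[tid],
            t_eval=datasets[tid].observed_days,
            rtol=rtol,
            atol=atol,
        )
        return residuals(traj, datasets[tid], scale=loss)

    def objective(x):
        return np.concatenate([arm_residuals(tid, x) for tid in order])

    best, n_ok, message = _run_multistart(objective, lo, hi, restarts, seed)
    bounds_dict = {name: tuple(bounds[name]) for name in _EPS_FIELDS}
    n_per = {tid: datasets[tid].n for tid in order}
    if best is None:
        return FitResult(
            variant=ModelVariant.DYNAMIC,
            params={},
            bounds=bounds_dict,
            per_therapy_rss={},
            n_per_therapy=n_per,
            k=len(_EPS_FIELDS),
            converged=False,
            n_restarts=restarts,
            seed=seed,
            message=f"no restart converged: {message}",
        )
    per_rss = {tid: float(np.sum(arm_residuals(tid, best.x) ** 2)) for tid in order}
    return FitResult(
        variant=ModelVariant.DYNAMIC,
        params={name: float(v) for name, v in zip(_EPS_FIELDS, best.x)},
        bounds=bounds_dict,
        per_therapy_rss=per_rss,
        n_per_therapy=n_per,
        k=len(_EPS_FIELDS),
        converged=True,
        n_restarts=restarts,
        seed=seed,
        message=message,
    )
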