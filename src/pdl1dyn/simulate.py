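"""Dosing schedules and event-aware ODE integration.

Doses are realized as instantaneous bolus additions to the drug
compartments: integration halts at each dose time, the compartment jumps
by the μg dose converted to compartment units, and integration restarts.
This matches the experimental protocol (IV Avelumab on days 0, 3 and 6;
a single subcutaneous NHS-muIL12 dose on day 0) without stiff
narrow-pulse forcing terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ModelVariant, _base_derivs, _eps_deriv, compute_Q
from .params import BaseParams, EpsilonParams

__all__ = [
    "DoseEvent",
    "TreatmentSchedule",
    "Trajectory",
    "IntegrationError",
    "STANDARD_DOSES",
    "AVELUMAB_DAYS",
    "standard_schedule",
    "standard_arms",
    "integrate",
]

#: Standard six-arm design: (Avelumab μg, NHS-muIL12 μg) per therapy.
STANDARD_DOSES: dict[str, tuple[float, float]] = {
    "a": (0.0, 0.0),  # isotype control
    "b": (0.0, 2.0),  # NHS-muIL12 2 μg
    "c": (0.0, 10.0),  # NHS-muIL12 10 μg
    "d": (200.0, 0.0),  # Avelumab 200 μg
    "e": (200.0, 2.0),  # combination, low-dose NHS
    "f": (200.0, 10.0),  # combination, high-dose NHS
}

#: Avelumab IV dosing days.
AVELUMAB_DAYS: tuple[float, ...] = (0.0, 3.0, 6.0)


@dataclass(frozen=True, order=True)
class DoseEvent:
    """A single bolus: ``compartment`` is ``"A1"`` (Avelumab) or ``"A2"``."""

    time: float
    compartment: str
    amount_ug: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.compartment not in ("A1", "A2"):
            raise ValueError(f"compartment must be 'A1' or 'A2', got {self.compartment!r}")
        if self.amount_ug < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount_ug}")


@dataclass
class TreatmentSchedule:
    """Ordered dose events for one therapy arm."""

    therapy_id: str
    events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.time, e.compartment))

    def dose_times(self) -> list[float]:
        return sorted({e.time for e in self.events})


def standard_schedule(
    therapy_id: str,
    avelumab_ug: float | None = None,
    nhs_ug: float | None = None,
) -> TreatmentSchedule:
    """Schedule for one arm of the standard design.

    With doses omitted, the therapy id is looked up in
    :data:`STANDARD_DOSES`.  Avelumab is dosed on days 0, 3 and 6 when
    its dose is positive; NHS-muIL12 once on day 0.
    """
    if avelumab_ug is None and nhs_ug is None:
        if therapy_id not in STANDARD_DOSES:
            raise KeyError(
                f"unknown therapy {therapy_id!r}; standard arms are {sorted(STANDARD_DOSES)}"
            )
        avelumab_ug, nhs_ug = STANDARD_DOSES[therapy_id]
    avelumab_ug = float(avelumab_ug or 0.0)
    nhs_ug = float(nhs_ug or 0.0)
    if avelumab_ug < 0 or nhs_ug < 0:
        raise ValueError("doses must be nonnegative")
    events = []
    if avelumab_ug > 0:
        events += [DoseEvent(t, "A1", avelumab_ug) for t in AVELUMAB_DAYS]
    if nhs_ug > 0:
        events.append(DoseEvent(0.0, "A2", nhs_ug))
    return TreatmentSchedule(therapy_id=therapy_id, events=events)


def standard_arms() -> dict[str, TreatmentSchedule]:
    """All six standard schedules keyed by therapy id."""
    return {tid: standard_schedule(tid) for tid in STANDARD_DOSES}


@dataclass
class Trajectory:
    """Dense simulated states over time for one arm.

    ``states`` has one row per time point and 4 (constant-ϵ) or 5
    (dynamic-ϵ) columns ``V, T, A1, A2[, eps]``; ``Q_series`` is the
    PD-1/PD-L1 complex recomputed from the states.  At a dose time the
    recorded state is the post-dose value.
    """

    times: np.ndarray
    states: np.ndarray
    Q_series: np.ndarray
    variant: ModelVariant
    therapy_id: str | None = None
    eps_constant: float | None = None

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def A1(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def A2(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def eps(self) -> np.ndarray:
        if self.variant is ModelVariant.DYNAMIC:
            return self.states[:, 4]
        return np.full_like(self.times, self.eps_constant)

    def volume_at(self, days) -> np.ndarray:
        """Tumor volume interpolated at the requested days."""
        days = np.asarray(days, dtype=float)
        if days.min() < self.times[0] - 1e-9 or days.max() > self.times[-1] + 1e-9:
            raise ValueError(
                f"requested days span [{days.min()}, {days.max()}] outside the "
                f"trajectory span [{self.times[0]}, {self.times[-1]}]"
            )
        return np.interp(days, self.times, self.V)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "therapy_id": self.therapy_id,
                "time_day": self.times,
                "V_mm3": self.V,
                "T_mm3": self.T,
                "A1": self.A1,
                "A2": self.A2,
                "eps": self.eps,
                "Q": self.Q_series,
            }
        )
        return df


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing interval."""


def _converted_bolus(event: DoseEvent, p: BaseParams) -> tuple[int, float]:
    idx = 2 if event.compartment == "A1" else 3
    scale = p.dose_scale_A1 if event.compartment == "A1" else p.dose_scale_A2
    return idx, event.amount_ug * scale


def integrate(
    p: BaseParams,
    schedule: TreatmentSchedule,
    *,
    variant: ModelVariant | str = ModelVariant.CONSTANT,
    eps: float | None = None,
    eps_params: EpsilonParams | None = None,
    V0: float = 100.0,
    T0: float | None = None,
    A0: tuple[float, float] = (0.0, 0.0),
    eps0: float | None = None,
    horizon: float = 30.0,
    grid: float = 0.1,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float | Sequence[float] | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one model variant over ``[0, horizon]`` with dose events.

    Parameters
    ----------
    eps
        Constant PD-L1 propensity (required for the constant variant).
    eps_params
        Parameters of the ϵ equation (required for the dynamic variant).
    T0
        Initial activated T-cell volume; defaults to the drug-free
        steady state ``lambda_T / d_T``.
    eps0
        Initial ϵ for the dynamic variant; defaults to the drug-free
        quasi-steady state at the initial tumor volume,
        ``k_basal·V0/(K_V+V0)/d_eps``.
    t_eval
        Explicit output times; otherwise a uniform grid of spacing
        ``grid`` plus all dose times.
    """
    variant = ModelVariant(variant)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if variant is ModelVariant.CONSTANT:
        if eps is None:
            raise ValueError("constant-eps variant requires eps")
        if eps < 0:
            raise ValueError("eps must be nonnegative")
    else:
        if eps_params is None:
            raise ValueError("dynamic variant requires eps_params")

    if T0 is None:
        T0 = p.lambda_T / p.d_T
    y0 = [V0, T0, A0[0], A0[1]]
    if variant is ModelVariant.DYNAMIC:
        if eps0 is None:
            eps0 = eps_params.k_basal * V0 / (eps_params.K_V + V0) / max(eps_params.d_eps, 1e-300)
            if eps_params.d_eps == 0:
                eps0 = 0.0
        y0.append(eps0)
    y0 = np.asarray(y0, dtype=float)
    if (y0 < 0).any():
        raise ValueError(f"initial state must be nonnegative, got {y0}")

    events = list(schedule.events)
    late = [e for e in events if e.time > horizon]
    if late:
        warnings.warn(
            f"{len(late)} dose event(s) beyond horizon={horizon} ignored", stacklevel=2
        )
        events = [e for e in events if e.time <= horizon]

    if t_eval is None:
        out_times = np.arange(0.0, horizon + 0.5 * grid, grid)
        out_times = np.unique(np.concatenate([out_times, [horizon], [e.time for e in events]]))
    else:
        out_times = np.unique(np.asarray(t_eval, dtype=float))
        if out_times.min() < 0 or out_times.max() > horizon + 1e-9:
            raise ValueError("t_eval must lie within [0, horizon]")
        out_times = np.unique(np.concatenate([out_times, [e.time for e in events if e.time <= out_times.max()]]))

    # clamped RHS: the solver may probe marginally negative values
    if variant is ModelVariant.CONSTANT:

        def rhs(t, y):
            V, T, A1, A2 = np.maximum(y, 0.0)
            return _base_derivs(V, T, A1, A2, eps, p)

    else:

        def rhs(t, y):
            V, T, A1, A2, e = np.maximum(y, 0.0)
            dV, dT, dA1, dA2 = _base_derivs(V, T, A1, A2, e, p)
            return dV, dT, dA1, dA2, _eps_deriv(V, A1, A2, e, eps_params, p)

    if atol is None:
        # per-component floors: the drug compartments live many orders of
        # magnitude below the tumor/T-cell scale, at the K_A1/K_A2 scale
        drug_floor = 1e-6 * min(p.K_A1, p.K_A2)
        atol = [1e-8, 1e-8, drug_floor, drug_floor]
        if variant is ModelVariant.DYNAMIC:
            atol.append(1e-8)

    # apply day-0 boluses
    y = y0.copy()
    for ev in events:
        if ev.time == 0.0:
            idx, amt = _converted_bolus(ev, p)
            y[idx] += amt

    seg_ends = sorted({e.time for e in events if 0.0 < e.time < horizon} | {horizon})
    t0 = 0.0
    times_acc = [np.array([0.0])]
    states_acc = [y.copy()[None, :]]
    for t1 in seg_ends:
        sol = solve_ivp(rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise IntegrationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
        tt = out_times[(out_times > t0) & (out_times < t1)]
        if tt.size:
            times_acc.append(tt)
            states_acc.append(sol.sol(tt).T)
        y = sol.y[:, -1].copy()
        for ev in events:
            if ev.time == t1:
                idx, amt = _converted_bolus(ev, p)
                y[idx] += amt
        if t1 in out_times:
            times_acc.append(np.array([t1]))
            states_acc.append(y.copy()[None, :])
        t0 = t1

    times = np.concatenate(times_acc)
    states = np.maximum(np.concatenate(states_acc, axis=0), 0.0)
    if t_eval is not None:
        keep = np.isin(times, np.asarray(t_eval, dtype=float)) | np.isin(times, out_times)
        times, states = times[keep], states[keep]
    eps_col = states[:, 4] if variant is ModelVariant.DYNAMIC else eps
    q_series = compute_Q(states[:, 1], states[:, 0], states[:, 2], eps_col, p)
    return Trajectory(
        times=times,
        states=states,
        Q_series=np.asarray(q_series, dtype=float),
        variant=variant,
        therapy_id=schedule.therapy_id,
        eps_constant=None if variant is ModelVariant.DYNAMIC else float(eps),
    )
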