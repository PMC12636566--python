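"""Right-hand sides of the constant-ϵ and dynamic-ϵ tumor–immune models.

State layout is ``[V, T, A1, A2]`` for the base (constant-ϵ) variant and
``[V, T, A1, A2, eps]`` for the dynamic variant.  The algebraic
PD-1/PD-L1 complex ``Q`` couples the compartments:

    Q = T·(T + eps·V) / (1 + A1/K_A1)

PD-1 lives on T cells, PD-L1 on both T and tumor cells (weighted by the
expression propensity ``eps``); Avelumab (A1) blocks complex formation.
Complex signaling inhibits T-cell killing of the tumor through the factor
``1/(1 + Q/K_Q)``:

    dV/dt  = r·V − η·T·V / (1 + Q/K_Q)
    dT/dt  = λ_T + λ_T8I12 · T/(1 + T/K_T) · A2/(K_A2 + A2) − d_T·T
    dA1/dt = −d_A1·A1        (doses enter as bolus events, see simulate)
    dA2/dt = −d_A2·A2

The dynamic variant adds an equation for tumor PD-L1 expression, the
model's encoding of adaptive immune resistance: upregulation saturating
in tumor volume, upregulation by NHS-muIL12, Michaelis–Menten
suppression by Avelumab, and first-order decay:

    deps/dt = k_basal·V/(K_V + V) + α_A2·A2/(K_A2 + A2)
              − α_A1·A1/(K_A1 + A1)·eps − d_eps·eps
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .params import BaseParams, EpsilonParams

__all__ = ["ModelVariant", "compute_Q", "base_rhs", "epsilon_rhs", "full_rhs"]


class ModelVariant(str, Enum):
    """Which ϵ treatment the model uses; fixes the state dimension."""

    CONSTANT = "constant"
    DYNAMIC = "dynamic"

    @property
    def dim(self) -> int:
        return 4 if self is ModelVariant.CONSTANT else 5


def _check_domain(**values) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if np.isnan(arr).any():
            raise FloatingPointError(f"NaN encountered in {name}")
        if (arr < 0).any():
            raise ValueError(f"{name} must be nonnegative, got {v!r}")


def compute_Q(T, V, A1, eps, p: BaseParams):
    """PD-1/PD-L1 complex level for given T-cell, tumor and drug levels.

    Vanishes when ``T == 0`` (no T cells means no PD-1), increases with
    T, V and eps, and is suppressed by Avelumab blockade through
    ``1/(1 + A1/K_A1)``.  Accepts scalars or broadcastable arrays.
    """
    _check_domain(T=T, V=V, A1=A1, eps=eps)
    T = np.asarray(T, dtype=float)
    q = T * (T + np.asarray(eps, dtype=float) * np.asarray(V, dtype=float))
    q = q / (1.0 + np.asarray(A1, dtype=float) / p.K_A1)
    return q if q.ndim else float(q)


def base_rhs(state, t: float, p: BaseParams, eps: float):
    """Time derivatives ``(dV, dT, dA1, dA2)`` of the base model.

    ``eps`` is the (instantaneous) PD-L1 expression propensity; between
    dose events the drug compartments decay exponentially.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (4,):
        raise ValueError(f"base model state must have 4 components, got shape {state.shape}")
    _check_domain(state=state, eps=eps)
    V, T, A1, A2 = state
    return np.array(_base_derivs(V, T, A1, A2, float(eps), p))


def epsilon_rhs(eps, V, A1, A2, q: EpsilonParams, p: BaseParams) -> float:
    """dϵ/dt of the dynamic PD-L1 expression equation."""
    _check_domain(eps=eps, V=V, A1=A1, A2=A2)
    return float(_eps_deriv(float(V), float(A1), float(A2), float(eps), q, p))


def full_rhs(state, t: float, p: BaseParams, q: EpsilonParams):
    """Derivatives ``(dV, dT, dA1, dA2, deps)`` of the dynamic model.

    The first four components coincide with :func:`base_rhs` evaluated
    at the instantaneous ``eps`` state.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ValueError(f"dynamic model state must have 5 components, got shape {state.shape}")
    _check_domain(state=state)
    V, T, A1, A2, eps = state
    dV, dT, dA1, dA2 = _base_derivs(V, T, A1, A2, eps, p)
    return np.array([dV, dT, dA1, dA2, _eps_deriv(V, A1, A2, eps, q, p)])


# --- unchecked kernels shared with the integrator ---------------------------


def _base_derivs(V, T, A1, A2, eps, p: BaseParams):
    q = T * (T + eps * V) / (1.0 + A1 / p.K_A1)
    kill = p.eta * T * V / (1.0 + q / p.K_Q)
    dV = p.r * V - kill
    stim = p.lambda_T8I12 * (T / (1.0 + T / p.K_T)) * A2 / (p.K_A2 + A2)
    dT = p.lambda_T + stim - p.d_T * T
    return dV, dT, -p.d_A1 * A1, -p.d_A2 * A2


def _eps_deriv(V, A1, A2, eps, q: EpsilonParams, p: BaseParams):
    up_tumor = q.k_basal * V / (q.K_V + V)
    up_drug = q.alpha_A2 * A2 / (p.K_A2 + A2)
    down_drug = q.alpha_A1 * (A1 / (p.K_A1 + A1)) * eps
    return up_tumor + up_drug - down_drug - q.d_eps * eps
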