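"""Parameter containers for the tumor–immune checkpoint model.

The model tracks tumor volume ``V`` (mm³), activated T-cell volume ``T``
(mm³), and two drug compartments: the anti-PD-L1 antibody Avelumab (``A1``)
and the IL-12 immunocytokine NHS-muIL12 (``A2``), both expressed in the
same unit system as their half-saturation constants ``K_A1`` and ``K_A2``.
PD-L1 expression propensity ``eps`` is either a fitted constant (base
model) or a fifth state variable with its own rate equation (dynamic
model); the parameters of that equation live in :class:`EpsilonParams`.

Drug clearance rates follow first-order kinetics, ``rate = ln 2 /
half-life``: Avelumab clears with a murine half-life of 1.86 days
(0.3726 day⁻¹) and NHS-muIL12 with 9.5 days (0.0730 day⁻¹).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import yaml

__all__ = [
    "BaseParams",
    "EpsilonParams",
    "half_life_to_rate",
    "params_to_yaml",
    "params_from_yaml",
]


def half_life_to_rate(t_half: float) -> float:
    """First-order clearance rate (day⁻¹) from a half-life in days.

    >>> round(half_life_to_rate(1.86), 4)
    0.3726
    """
    if not t_half > 0:
        raise ValueError(f"half-life must be positive, got {t_half!r}")
    return math.log(2.0) / t_half


@dataclass(frozen=True)
class BaseParams:
    """Rate and saturation constants of the four-compartment base model.

    Attributes
    ----------
    r : float
        Tumor proliferation rate, day⁻¹.
    eta : float
        T-cell kill-rate coefficient, day⁻¹ per mm³ of T cells.
    lambda_T : float
        Basal activated T-cell production, mm³·day⁻¹.
    lambda_T8I12 : float
        Maximal NHS-muIL12-driven T-cell stimulation rate, day⁻¹.
    d_T : float
        Activated T-cell turnover rate, day⁻¹.
    d_A1, d_A2 : float
        First-order drug clearance rates, day⁻¹ (murine half-lives of
        1.86 d for Avelumab and 9.5 d for NHS-muIL12).
    K_A1, K_A2 : float
        Half-saturation constants of the two drug compartments.
    K_Q : float
        PD-1/PD-L1 complex level at which T-cell killing is halved.
    K_T : float
        Crowding scale (mm³) at which antigen-driven T-cell stimulation
        saturates in the T-cell level itself.
    dose_scale_A1, dose_scale_A2 : float
        Conversion from an administered dose in μg to compartment units
        (the unit system of ``K_A1``/``K_A2``). The magnitudes of these
        constants are the one deliberately configurable unit bridge in
        the model.
    """

    r: float = 0.25
    eta: float = 0.1
    lambda_T: float = 4.5
    lambda_T8I12: float = 4.15
    d_T: float = 2.0
    d_A1: float = half_life_to_rate(1.86)  # 0.3726 day^-1
    d_A2: float = half_life_to_rate(9.5)  # 0.0730 day^-1
    K_A1: float = 1e-13
    K_A2: float = 7e-14
    K_Q: float = 1e4
    K_T: float = 50.0
    dose_scale_A1: float = 1e-13
    dose_scale_A2: float = 7e-14

    def __post_init__(self) -> None:
        # rates may be zero (degenerate/extinction configurations are valid
        # test points); saturation constants and dose scales must be positive
        for name in ("r", "eta", "lambda_T", "lambda_T8I12", "d_T", "d_A1", "d_A2"):
            value = getattr(self, name)
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"BaseParams.{name} must be nonnegative, got {value!r}")
        for name in ("K_A1", "K_A2", "K_Q", "K_T", "dose_scale_A1", "dose_scale_A2"):
            value = getattr(self, name)
            if not value > 0 or not math.isfinite(value):
                raise ValueError(f"BaseParams.{name} must be strictly positive, got {value!r}")

    def replace(self, **changes) -> "BaseParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EpsilonParams:
    """Parameters of the dynamic PD-L1 expression equation.

    All rates are day⁻¹; ``K_V`` is a tumor volume in mm³. Defaults are
    the globally fitted values of the dynamic model: tumor-size-driven
    upregulation ``k_basal`` saturating at half-volume ``K_V``,
    Avelumab-induced suppression ``alpha_A1``, NHS-muIL12-induced
    upregulation ``alpha_A2`` (the adaptive-resistance term), and natural
    decay ``d_eps``.
    """

    k_basal: float = 30.5441
    K_V: float = 50.0
    alpha_A1: float = 38.2653
    alpha_A2: float = 643.6397
    d_eps: float = 0.4409

    def __post_init__(self) -> None:
        for name in ("k_basal", "K_V", "alpha_A1", "alpha_A2", "d_eps"):
            value = getattr(self, name)
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"EpsilonParams.{name} must be nonnegative, got {value!r}")
        if not self.K_V > 0:
            raise ValueError(f"EpsilonParams.K_V must be positive, got {self.K_V!r}")

    def replace(self, **changes) -> "EpsilonParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def as_array(self):
        return [self.k_basal, self.K_V, self.alpha_A1, self.alpha_A2, self.d_eps]

    @classmethod
    def zero(cls) -> "EpsilonParams":
        """Degenerate parameter set freezing eps at its initial value."""
        return cls(k_basal=0.0, K_V=1.0, alpha_A1=0.0, alpha_A2=0.0, d_eps=0.0)


def params_to_yaml(base: BaseParams, eps: EpsilonParams | None = None) -> str:
    """Serialize parameter sets to a flat key–value YAML document."""
    payload: dict = {"base": base.to_dict()}
    if eps is not None:
        payload["epsilon"] = eps.to_dict()
    return yaml.safe_dump(payload, sort_keys=False)


def params_from_yaml(text: str) -> tuple[BaseParams, EpsilonParams | None]:
    """Inverse of :func:`params_to_yaml`; unknown keys are rejected."""
    payload: Mapping = yaml.safe_load(text)
    base = BaseParams(**payload["base"])
    eps = EpsilonParams(**payload["epsilon"]) if "epsilon" in payload else None
    return base, eps
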