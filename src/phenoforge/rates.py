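"""Temperature-dependent developmental-rate equations.

Four rate families describe how daily mean air temperature drives
developmental progress toward a spring phenological event:

* ``linear`` — r = a + b*T, clipped at zero below the biological zero
  T0 = -a/b (development cannot regress);
* ``arrhenius`` — r = 1e12 * exp(B - Ea / (R*T_K)), an exponential increase
  with absolute temperature T_K = T + 273.15; the 1e12 pre-exponential scale
  keeps B in a convenient range during estimation;
* ``logan`` — a left-skewed bell: r = psi * (exp(rho*T) -
  exp(rho*T_u - (T_u - T)/z)), zero at the upper lethal temperature T_u;
* ``logistic`` — a sigmoid r = K / (1 + (K/K0 - 1) * exp(-b*T)) with
  asymptote K and initial rate K0 at T = 0 degC.

All equations take temperature in degC; Kelvin conversion (exactly +273.15)
happens only inside the Arrhenius forms.  Rates are floored at zero.

The days-transferred-to-standard-temperature (DTS) kernel
``dts(T) = exp(Ea*(T_K - T_s) / (R*T_K*T_s))`` is the Arrhenius ratio of the
developmental rate at T to the rate at the standard temperature T_s
(25 degC = 298.15 K): one day at T counts as ``dts(T)`` days at T_s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_KCAL",
    "T_STANDARD_K",
    "PRE_EXP_SCALE",
    "RateModel",
    "rate_model",
    "dts",
    "celsius_to_kelvin",
]

#: universal gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987e-3
#: standard temperature for the DTS kernel: 25 degC in K
T_STANDARD_K = 298.15
#: pre-exponential scale of the Arrhenius rate equation
PRE_EXP_SCALE = 1e12

_FAMILY_PARAMS = {
    "linear": ("a", "b"),
    "arrhenius": ("B", "Ea"),
    "logan": ("psi", "rho", "Tu", "z"),
    "logistic": ("K", "K0", "b"),
}


def celsius_to_kelvin(t):
    return np.asarray(t, dtype=float) + 273.15


def dts(t, e_a: float, t_s: float = T_STANDARD_K):
    """DTS factor exp(Ea*(T_K - T_s)/(R*T_K*T_s)) for temperature ``t`` in degC.

    Equals 1 at T_K = t_s and is strictly increasing in ``t`` for Ea > 0.
    """
    t_k = celsius_to_kelvin(t)
    if np.any(t_k <= 0):
        raise ValueError("temperature at or below absolute zero")
    return np.exp(e_a * (t_k - t_s) / (R_KCAL * t_k * t_s))


@dataclass
class RateModel:
    """A rate-equation family plus its parameter vector.

    Use :func:`rate_model` or ``RateModel.from_dict`` to construct; parameters
    are validated against the family's signature.
    """

    family: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(
                f"unknown rate family {self.family!r}; known: {sorted(_FAMILY_PARAMS)}"
            )
        expected = _FAMILY_PARAMS[self.family]
        missing = [p for p in expected if p not in self.params]
        if missing:
            raise ValueError(f"{self.family} rate model missing parameters {missing}")
        for name, value in self.params.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"non-finite parameter {name}={value}")
        if self.family == "logan" and self.params["z"] == 0:
            raise ValueError("logan z must be nonzero")
        if self.family == "logistic" and not (0.0 < self.params["K0"] < self.params["K"]):
            raise ValueError("logistic requires 0 < K0 < K")

    @property
    def param_vector(self) -> np.ndarray:
        return np.array([self.params[p] for p in _FAMILY_PARAMS[self.family]], float)

    def with_params(self, vector) -> "RateModel":
        names = _FAMILY_PARAMS[self.family]
        return RateModel(self.family, dict(zip(names, map(float, vector))))

    def rate(self, t):
        """Developmental rate (day^-1) at temperature ``t`` (degC), floored at 0."""
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "linear":
            r = p["a"] + p["b"] * t
        elif self.family == "arrhenius":
            r = PRE_EXP_SCALE * np.exp(p["B"] - p["Ea"] / (R_KCAL * celsius_to_kelvin(t)))
        elif self.family == "logan":
            r = p["psi"] * (
                np.exp(p["rho"] * t) - np.exp(p["rho"] * p["Tu"] - (p["Tu"] - t) / p["z"])
            )
        else:  # logistic
            r = p["K"] / (1.0 + (p["K"] / p["K0"] - 1.0) * np.exp(-p["b"] * t))
        return np.maximum(r, 0.0)

    def reciprocal_duration(self, t) -> float:
        """Developmental duration 1/r in days at constant temperature ``t``."""
        r = float(self.rate(t))
        if r <= 0.0:
            raise ZeroDivisionError(
                f"rate is zero at {t} degC for {self.family}: infinite duration"
            )
        return 1.0 / r

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "params": self.params})

    @classmethod
    def from_json(cls, text: str) -> "RateModel":
        d = json.loads(text)
        return cls(d["family"], d["params"])

    @classmethod
    def from_dict(cls, d: dict) -> "RateModel":
        return cls(d["family"], dict(d["params"]))


def rate_model(family: str, **params: float) -> RateModel:
    """Convenience constructor: ``rate_model('arrhenius', B=-4.38, Ea=15.04)``."""
    return RateModel(family, params)
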