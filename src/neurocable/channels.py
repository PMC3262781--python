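"""Hodgkin-Huxley style gate kinetics and channel currents.

A voltage-gated channel carries gates (``m``, ``h``, ``n``...) whose
opening and closing rates α(Vm), β(Vm) take one of three classic
functional forms:

* ``linoid``       A·(V½ − Vm) / (exp((V½ − Vm)/σ) − 1), with the
  removable singularity at Vm = V½ evaluated by its limit A·σ;
* ``exponential``  A·exp(−(Vm − V½)/σ);
* ``sigmoid``      A / (exp((V½ − Vm)/σ) + 1).

All rates are s⁻¹ and all voltages absolute membrane potential in V.
The steady state of a gate is x∞ = α/(α+β) and its time constant
τ = 1/(α+β).

The registry below holds the squid-axon sodium and potassium kinetics
(6.3 °C, rest at −0.070 V) shipped with the channel library file
``channels/hodgkin-huxley.ndf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: half-width of the window around the linoid singularity evaluated by limit
_LINOID_EPS = 1e-9


@dataclass(frozen=True)
class RateFunction:
    """One α or β rate as a function of membrane potential."""

    form: str  # linoid | exponential | sigmoid
    A: float  # rate amplitude, s⁻¹ (s⁻¹·V⁻¹ for linoid)
    offset: float  # V½, V
    scale: float  # σ, V

    def __post_init__(self) -> None:
        if self.form not in ("linoid", "exponential", "sigmoid"):
            raise ValueError(f"unknown rate form {self.form!r}")
        if self.scale == 0:
            raise ValueError("rate scale must be nonzero")

    def __call__(self, Vm: float) -> float:
        if not math.isfinite(Vm):
            raise ValueError("Vm must be finite")
        x = self.offset - Vm
        if self.form == "linoid":
            if abs(x) < _LINOID_EPS:
                return self.A * self.scale  # L'Hôpital limit at the pole
            return self.A * x / (math.exp(x / self.scale) - 1.0)
        if self.form == "exponential":
            return self.A * math.exp(x / self.scale)
        return self.A / (math.exp(x / self.scale) + 1.0)


@dataclass(frozen=True)
class GateKinetics:
    alpha: RateFunction
    beta: RateFunction

    def rates(self, Vm: float) -> tuple[float, float]:
        return self.alpha(Vm), self.beta(Vm)

    def steady_state(self, Vm: float) -> float:
        a, b = self.rates(Vm)
        return a / (a + b)

    def time_constant(self, Vm: float) -> float:
        a, b = self.rates(Vm)
        return 1.0 / (a + b)


#: Squid-axon kinetics, SI units, rest at −0.070 V.
KINETICS: dict[str, GateKinetics] = {
    "hh_na_m": GateKinetics(
        alpha=RateFunction("linoid", 1e5, -0.045, 0.010),
        beta=RateFunction("exponential", 4e3, -0.070, 0.018),
    ),
    "hh_na_h": GateKinetics(
        alpha=RateFunction("exponential", 70.0, -0.070, 0.020),
        beta=RateFunction("sigmoid", 1e3, -0.040, 0.010),
    ),
    "hh_k_n": GateKinetics(
        alpha=RateFunction("linoid", 1e4, -0.060, 0.010),
        beta=RateFunction("exponential", 125.0, -0.070, 0.080),
    ),
}


def get_kinetics(kinetics_id: str) -> GateKinetics:
    try:
        return KINETICS[kinetics_id]
    except KeyError:
        raise KeyError(f"unknown gate kinetics id {kinetics_id!r}") from None


def rate(which: str, kinetics_id: str, Vm: float) -> float:
    """Evaluate the α or β rate (s⁻¹) of a registered gate at Vm."""
    k = get_kinetics(kinetics_id)
    if which == "alpha":
        return k.alpha(Vm)
    if which == "beta":
        return k.beta(Vm)
    raise ValueError("which must be 'alpha' or 'beta'")


def steady_state(kinetics_id: str, Vm: float) -> float:
    return get_kinetics(kinetics_id).steady_state(Vm)


def time_constant(kinetics_id: str, Vm: float) -> float:
    return get_kinetics(kinetics_id).time_constant(Vm)


def channel_current(gbar: float, erev: float, gates: dict[str, float],
                    powers: dict[str, int], Vm: float, area: float) -> float:
    """Ohmic channel current, positive outward:
    I = GBAR·area·(∏ x_g^p_g)·(Vm − EREV)."""
    open_fraction = 1.0
    for g, p in powers.items():
        x = gates[g]
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"gate {g} out of [0, 1]: {x}")
        open_fraction *= x ** p
    return gbar * area * open_fraction * (Vm - erev)
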