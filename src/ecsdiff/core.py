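"""Closed-form point-source diffusion in brain extracellular space.

An iontophoretic micropipette releases a small inert cation (TMA+) into
the extracellular space (ECS); an ion-selective microelectrode 100-150 um
away records the concentration transient.  In an isotropic medium with
volume fraction ``alpha``, tortuosity ``lam`` and first-order nonspecific
uptake ``kprime``, the concentration increment produced by a constant
current step of duration ``T`` at distance ``r`` from the source is

    C(r, t) = Q / (8 pi D* alpha r)
              * [ exp( r b) erfc(r / (2 sqrt(D* t)) + sqrt(k' t))
                + exp(-r b) erfc(r / (2 sqrt(D* t)) - sqrt(k' t)) ]

for 0 < t <= T, with D* = D / lam**2 the effective diffusion coefficient,
b = sqrt(k'/D*) and Q the molar release rate; for t > T the falling phase
follows by linear superposition, C(r, t) - C(r, t - T).

Internal unit conventions used throughout the package: lengths in um,
times in s, concentrations in uM.  Diffusion coefficients are accepted in
the customary cm^2/s and converted on entry (1 cm^2/s = 1e8 um^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import erfcx

__all__ = [
    "FARADAY",
    "CM2_TO_UM2",
    "MOL_PER_UM3_TO_UM",
    "ECSParameters",
    "IontophoreticSource",
    "DiffusionCurve",
    "CalibrationTable",
    "effective_diffusion",
    "source_strength",
    "point_source_concentration",
    "bias_steady_state",
    "generate_curve",
]

FARADAY = 96485.33212  # C/mol
CM2_TO_UM2 = 1e8  # 1 cm^2/s in um^2/s
#: 1 mol/um^3 expressed in uM (1 um^3 = 1e-15 L; 1 mol/L = 1e6 uM).
MOL_PER_UM3_TO_UM = 1e21


@dataclass(frozen=True)
class ECSParameters:
    """Extracellular-space geometry and nonspecific loss.

    alpha
        ECS volume fraction (ECS volume / total tissue volume), in (0, 1].
    lam
        Tortuosity; lam**2 = D / ADC.  Physically >= 1, but fit bounds
        allow values down to 0.9 so that noise on free-medium curves does
        not pin the estimate at the boundary.
    kprime
        Nonspecific first-order uptake rate of the tracer, 1/s.
    """

    alpha: float
    lam: float
    kprime: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lam < 0.9:
            raise ValueError(f"lam must be >= 0.9, got {self.lam}")
        if self.kprime < 0.0:
            raise ValueError(f"kprime must be >= 0, got {self.kprime}")


@dataclass(frozen=True)
class IontophoreticSource:
    """Current protocol and electrode properties defining source strength.

    The transport number is the fraction of the iontophoretic current
    actually carried by the tracer ion; together with the valence it
    converts current to a molar release rate.
    """

    bias_current: float = 20.0  # nA, applied continuously
    step_current: float = 180.0  # nA, the measurement step
    pulse_duration: float = 24.0  # s
    transport_number: float = 0.3
    free_D: float = 1.24e-5  # cm^2/s
    valence: int = 1

    def __post_init__(self) -> None:
        if self.step_current <= 0:
            raise ValueError("step_current must be > 0")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0")
        if not 0.0 < self.transport_number <= 1.0:
            raise ValueError("transport_number must be in (0, 1]")
        if self.free_D <= 0:
            raise ValueError("free_D must be > 0")
        if self.bias_current < 0:
            raise ValueError("bias_current must be >= 0")


@dataclass
class DiffusionCurve:
    """One concentration-time record at a known source-sensor distance.

    Concentrations are increments above the bias-current baseline, in uM.
    ``medium`` distinguishes the free-diffusion agar reference from brain
    tissue.
    """

    distance: float  # um
    times: np.ndarray  # s
    concentration: np.ndarray  # uM
    medium: Literal["agar", "tissue"] = "tissue"
    depth: float = float("nan")  # um below cortical surface
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.shape != self.concentration.shape:
            raise ValueError("times and concentration must have equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.distance <= 0:
            raise ValueError("distance must be > 0")

    @property
    def peak(self) -> float:
        return float(np.max(self.concentration)) if self.concentration.size else 0.0


@dataclass
class CalibrationTable:
    """Electrode calibration points: TMA+ concentration (mM) vs voltage (mV)."""

    concentrations: np.ndarray  # mM
    voltages: np.ndarray  # mV

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.concentrations.shape != self.voltages.shape:
            raise ValueError("concentrations and voltages must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.concentrations.size > 1 and not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be strictly increasing")


def effective_diffusion(free_D: float, lam: float) -> float:
    """Effective (apparent) diffusion coefficient D* = D / lam**2, cm^2/s."""
    if free_D <= 0 or lam <= 0:
        raise ValueError("free_D and lam must be > 0")
    return free_D / lam**2


def source_strength(source: IontophoreticSource, current: float) -> float:
    """Molar release rate Q = I * n_t / (z * F) for a given current (nA).

    Returns mol/s.
    """
    if current < 0:
        raise ValueError("current must be >= 0")
    return current * 1e-9 * source.transport_number / (abs(source.valence) * FARADAY)


def _step_response(
    r: float, t: np.ndarray, Q: float, D_star: float, alpha: float, kprime: float
) -> np.ndarray:
    """Concentration (uM) for a step source switched on at t=0, vectorised in t.

    The exp(+x)*erfc(y) products are evaluated through the scaled
    complementary error function: with a = r/(2 sqrt(D* t)) and
    b = sqrt(k' t) one has r*sqrt(k'/D*) = 2ab, so

        exp(2ab) erfc(a+b) + exp(-2ab) erfc(a-b)
            = exp(-a^2 - b^2) * [erfcx(a+b) + erfcx(a-b)],

    which cannot overflow for any admissible a, b >= 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    a = r / (2.0 * np.sqrt(D_star * tp))
    b = np.sqrt(kprime * tp)
    pref = Q * MOL_PER_UM3_TO_UM / (8.0 * np.pi * D_star * alpha * r)
    out[pos] = pref * np.exp(-(a**2) - b**2) * (erfcx(a + b) + erfcx(a - b))
    return out


def point_source_concentration(
    r: float,
    t: float | np.ndarray,
    source: IontophoreticSource,
    ecs: ECSParameters,
) -> float | np.ndarray:
    """Concentration increment (uM) above the bias baseline at distance r, time t.

    During the current step the two-term erfc solution applies; after the
    step ends the falling phase is the superposition of the step switched
    on at 0 and an equal negative step switched on at ``pulse_duration``.
    """
    if r <= 0:
        raise ValueError("r must be > 0 (the point source is singular at r = 0)")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    D_star = effective_diffusion(source.free_D, ecs.lam) * CM2_TO_UM2  # um^2/s
    Q = source_strength(source, source.step_current)
    c = _step_response(r, t_arr, Q, D_star, ecs.alpha, ecs.kprime)
    after = t_arr > source.pulse_duration
    if np.any(after):
        c[after] -= _step_response(
            r, t_arr[after] - source.pulse_duration, Q, D_star, ecs.alpha, ecs.kprime
        )
    return c if np.ndim(t) else float(c[0])


def bias_steady_state(
    r: float, source: IontophoreticSource, ecs: ECSParameters
) -> float:
    """Steady-state baseline (uM) maintained by the continuous bias current.

    The t -> infinity limit of the step response:
    C_b(r) = Q_b / (4 pi D* alpha r) * exp(-r sqrt(k'/D*)).
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if source.bias_current == 0:
        return 0.0
    D_star = effective_diffusion(source.free_D, ecs.lam) * CM2_TO_UM2
    Q_b = source_strength(source, source.bias_current)
    return float(
        Q_b
        * MOL_PER_UM3_TO_UM
        / (4.0 * np.pi * D_star * ecs.alpha * r)
        * np.exp(-r * np.sqrt(ecs.kprime / D_star))
    )


def generate_curve(
    source: IontophoreticSource,
    ecs: ECSParameters,
    r: float,
    times: np.ndarray,
    medium: Literal["agar", "tissue"] = "tissue",
    depth: float = float("nan"),
    animal_id: str = "",
    group: str = "",
) -> DiffusionCurve:
    """Sample the noiseless forward model on a time grid."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(point_source_concentration(r, times, source, ecs))
    return DiffusionCurve(
        distance=r,
        times=times,
        concentration=conc,
        medium=medium,
        depth=depth,
        animal_id=animal_id,
        group=group,
    )


def default_times(
    pulse_duration: float = 24.0, decay: float = 48.0, rate_hz: float = 5.0
) -> np.ndarray:
    """Default sampling grid: the rise phase plus a decay tail, at 5 Hz."""
    n = int(round((pulse_duration + decay) * rate_hz))
    return np.arange(n + 1) / rate_hz
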