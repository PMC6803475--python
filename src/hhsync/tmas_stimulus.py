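"""Magneto-acoustic stimulus current.

Transcranial magneto-acoustical stimulation (TMAS) drives ions with an
ultrasonic pressure wave inside a static magnetic field; the resulting
Lorentz force produces a current density

    J_y = sigma * B_x * sqrt(2 Gamma / (rho c0)) * sin(2 pi f t)

whose peak value depends on tissue conductivity ``sigma``, magnetic flux
density ``B_x``, ultrasonic intensity ``Gamma``, tissue density ``rho`` and
sound speed ``c0``.  The ultrasound carrier at frequency ``f`` is amplitude
modulated by a slower sine at the modulation frequency ``mf``, giving the
stimulus waveform

    I_ext(t) = amplitude * sin(2 pi mf t) * (sin(2 pi f t) + 1)

The two neurons receive the same carrier but different modulation
frequencies (100 and 104 Hz by default), which is what desynchronizes them
in open loop.  ``amplitude_scale`` is an explicit dimensionless bridge
between the physical A/m^2 value and the membrane-equation current units;
the dimensionless working regime of the study is reproduced with the
default of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TMASParameters",
    "TABLE_DEFAULTS",
    "current_amplitude",
    "modulation_envelope",
    "stimulus_current",
]

#: W/cm^2 -> W/m^2
_WCM2_TO_WM2 = 1.0e4


@dataclass(frozen=True)
class TMASParameters:
    """Physical constants of the magneto-acoustic stimulus.

    Parameters
    ----------
    sigma : float
        Tissue conductivity (S/m).
    B_x : float
        Static magnetic flux density (T).
    Gamma : float
        Ultrasonic intensity (W/cm^2, stored as given; converted internally).
    rho : float
        Tissue density (kg/m^3).
    c0 : float
        Speed of sound in tissue (m/s).
    f : float
        Ultrasonic carrier frequency (Hz).
    mf : float
        Modulation frequency (Hz); zero switches the stimulus off.
    amplitude_scale : float
        Dimensionless conversion applied to the computed current density
        before it is used as the membrane stimulus current.
    """

    sigma: float = 0.5
    B_x: float = 7.0
    Gamma: float = 100.0
    rho: float = 1120.0
    c0: float = 1540.0
    f: float = 200.0
    mf: float = 100.0
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma", "rho", "c0", "f"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"TMAS parameter {name} must be positive, got {getattr(self, name)}")
        for name in ("B_x", "Gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"TMAS parameter {name} must be nonnegative, got {getattr(self, name)}")
        if self.mf < 0:
            raise ValueError(f"modulation frequency must be nonnegative, got {self.mf}")

    def with_mf(self, mf: float) -> "TMASParameters":
        return replace(self, mf=mf)


#: The study's physical constants (sigma 0.5 S/m, B_x 7 T, Gamma 100 W/cm^2,
#: rho 1120 kg/m^3, c0 1540 m/s, carrier 200 Hz).
TABLE_DEFAULTS = TMASParameters()


def current_amplitude(params: TMASParameters) -> float:
    """Peak Lorentz-force current density sigma*B_x*sqrt(2 Gamma/(rho c0)) in A/m^2."""
    denom = params.rho * params.c0
    if denom <= 0:
        raise ValueError(f"rho*c0 must be positive, got {denom}")
    gamma_si = params.Gamma * _WCM2_TO_WM2
    return params.sigma * params.B_x * math.sqrt(2.0 * gamma_si / denom)


def modulation_envelope(t, mf: float, f: float):
    """Dimensionless modulated-carrier factor sin(2 pi mf t) * (sin(2 pi f t) + 1).

    Accepts scalar or array ``t``; the value lies in [-2, 2] and vanishes
    identically when ``mf`` is zero.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    out = np.sin(2.0 * np.pi * mf * t) * (np.sin(2.0 * np.pi * f * t) + 1.0)
    return out if out.ndim else float(out)


def stimulus_current(t, params: TMASParameters):
    """Stimulus current I_ext(t) = amplitude * envelope * amplitude_scale.

    A pure, deterministic function of ``t`` (scalar or array).  Bounded by
    ``2 * current_amplitude(params) * amplitude_scale`` in absolute value,
    and exactly periodic when ``f / mf`` is rational.
    """
    amp = current_amplitude(params) * params.amplitude_scale
    return amp * modulation_envelope(t, params.mf, params.f)
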