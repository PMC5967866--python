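"""Electrochemistry: Nernst diffusion potentials and single-channel conductance.

A K+-selective ionophore (valinomycin) clamps the membrane potential of a
vesicle at the K+ Nernst value E = (RT/zF) ln([K+]_out/[K+]_in), so a
10-fold outward K+ gradient gives ~+59 mV (inside positive) at 25 C and a
100-fold gradient ~+118 mV. Single-channel conductance is the slope of the
unitary current-voltage relation from planar-bilayer recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .units import CONSTANTS, T_STANDARD


class ElectroError(ValueError):
    """Raised for invalid electrochemical inputs."""


@dataclass(frozen=True)
class PotentialCondition:
    """Ion distribution for a Nernst-potential computation.

    k_in / k_out in mM (any common unit — only the ratio matters),
    temperature in K, z the ion charge number.
    """

    k_in: float
    k_out: float
    temperature: float = T_STANDARD
    z: int = 1

    def __post_init__(self) -> None:
        if self.k_in <= 0 or self.k_out <= 0:
            raise ElectroError(
                f"ion concentrations must be > 0, got in={self.k_in}, out={self.k_out}"
            )
        if self.z == 0:
            raise ElectroError("ion charge z must be nonzero")
        if self.temperature <= 0:
            raise ElectroError(f"temperature must be > 0 K, got {self.temperature}")


@dataclass
class IVTable:
    """Single-channel current-voltage table: voltage (mV) vs unitary current (pA)."""

    voltage: np.ndarray   # mV
    current: np.ndarray   # pA

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape:
            raise ElectroError("voltage and current must have equal length")
        if len(self.voltage) < 3:
            raise ElectroError("need >= 3 I-V points")
        if len(np.unique(self.voltage)) < 2:
            raise ElectroError("all voltages identical: slope undefined")


@dataclass
class ChannelFit:
    """Ohmic fit of an I-V table: conductance, reversal potential, diagnostics."""

    conductance: float          # pS
    reversal_potential: float   # mV
    r_squared: float
    conductance_se: float       # pS
    extrapolated_reversal: bool  # True when V_rev lies outside the measured range

    def as_dict(self) -> dict:
        return {
            "conductance": {"value": self.conductance, "unit": "pS"},
            "conductance_se": {"value": self.conductance_se, "unit": "pS"},
            "reversal_potential": {"value": self.reversal_potential, "unit": "mV"},
            "r_squared": {"value": self.r_squared, "unit": "dimensionless"},
            "extrapolated_reversal": self.extrapolated_reversal,
        }


def nernst_potential(cond: PotentialCondition) -> float:
    """Equilibrium (Nernst) potential in mV: E = (RT/zF) ln(out/in).

    Positive values mean inside-positive for a cation with k_out > k_in.
    """
    e_volts = (
        CONSTANTS.R * cond.temperature / (cond.z * CONSTANTS.F)
        * math.log(cond.k_out / cond.k_in)
    )
    return e_volts * 1000.0


def conductance_from_iv(iv: IVTable) -> ChannelFit:
    """Single-channel conductance from an ohmic I-V fit.

    Ordinary least squares of current (pA) on voltage (mV): the slope in
    pA/mV is a conductance in nS, reported in pS; the reversal potential
    is the zero-current voltage -intercept/slope.
    """
    res = stats.linregress(iv.voltage, iv.current)
    if res.slope == 0:
        raise ElectroError("zero slope: reversal potential undefined")
    v_rev = -res.intercept / res.slope
    return ChannelFit(
        conductance=float(res.slope * 1000.0),           # pA/mV = nS -> pS
        reversal_potential=float(v_rev),
        r_squared=float(res.rvalue**2),
        conductance_se=float(res.stderr * 1000.0),
        extrapolated_reversal=bool(
            v_rev < iv.voltage.min() or v_rev > iv.voltage.max()
        ),
    )
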