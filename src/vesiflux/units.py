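"""Physical constants and unit conversions.

All interface quantities use bench units (nm, uL, mg, mM, pA, mV, pS);
internal arithmetic is SI. Every power of ten lives here so the rest of
the package never multiplies by a bare 1e-9.
"""

from dataclasses import dataclass

# CODATA 2018 exact values
AVOGADRO = 6.02214076e23      # mol^-1
GAS_CONSTANT = 8.314462618    # J mol^-1 K^-1
FARADAY = 96485.33212         # C mol^-1

T_STANDARD = 298.15           # K, default assay temperature

# 1 Ci = 3.7e10 Bq = 2.22e12 dpm; 1 mCi = 2.22e9 dpm
DPM_PER_MCI = 2.22e9

NM3_TO_L = 1e-24      # 1 nm^3 = 1e-24 L
UL_TO_L = 1e-6
MG_PER_UL_TO_G_PER_L = 1e3    # mg/uL == g/mL == 1000 g/L
MM_TO_M = 1e-3
NMOL_TO_MOL = 1e-9
MOL_TO_MMOL = 1e3
SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants used by the electrochemistry code."""

    R: float = GAS_CONSTANT
    F: float = FARADAY
    N_A: float = AVOGADRO
    T_default: float = T_STANDARD


CONSTANTS = PhysicalConstants()
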