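"""Proteoliposome geometry: lipid counts, vesicle number, internal volume.

The central quantity of a reconstituted flux assay is the total
intraliposomal aqueous volume V_PL: it converts moles of accumulated
radiotracer into an internal concentration, which is what distinguishes
a channel (equilibrative, fold-accumulation ~1) from an ion-coupled
transporter (concentrative, fold >> 1).

The chain, for monodisperse unilamellar vesicles of outer radius r and
bilayer thickness m, with area a per lipid headgroup and average lipid
molar mass M:

    N_totPL = (4*pi*r^2 + 4*pi*(r-m)^2) / a        lipids per vesicle
    c_lipid = (lipid mass / assay volume) / M      mol/L
    N_PL/L  = c_lipid * N_A / N_totPL              vesicles per litre
    V_PL    = (4/3)*pi*(r-m)^3 * N_PL(in assay)    total internal volume

The outer and inner monolayers are counted at radii r and r-m; the inner
aqueous compartment has radius r-m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .units import AVOGADRO, MG_PER_UL_TO_G_PER_L, NM3_TO_L, UL_TO_L


class GeometryError(ValueError):
    """Raised for physically impossible vesicle or assay parameters."""


@dataclass(frozen=True)
class LiposomeSpec:
    """Geometric and chemical description of a unilamellar vesicle.

    Parameters
    ----------
    r_outer : float
        External vesicle radius, nm (50 nm for a 100-nm liposome).
    m_membrane : float
        Bilayer thickness, nm (typically 4 nm).
    a_headgroup : float
        Area per lipid headgroup, nm^2 (0.7 nm^2 for typical phospholipids).
    lipid_mw : float
        Average lipid molar mass, g/mol.
    """

    r_outer: float
    m_membrane: float
    a_headgroup: float
    lipid_mw: float

    def __post_init__(self) -> None:
        if self.m_membrane <= 0:
            raise GeometryError(f"membrane thickness must be > 0, got {self.m_membrane}")
        if self.r_outer <= self.m_membrane:
            raise GeometryError(
                f"outer radius ({self.r_outer} nm) must exceed membrane "
                f"thickness ({self.m_membrane} nm): inner radius would be <= 0"
            )
        if self.a_headgroup <= 0:
            raise GeometryError(f"headgroup area must be > 0, got {self.a_headgroup}")
        if self.lipid_mw <= 0:
            raise GeometryError(f"lipid molar mass must be > 0, got {self.lipid_mw}")

    @property
    def r_inner(self) -> float:
        """Inner (aqueous compartment) radius, nm."""
        return self.r_outer - self.m_membrane


@dataclass(frozen=True)
class AssaySpec:
    """Composition of one flux assay.

    Parameters
    ----------
    lipid_mass : float
        Total lipid in the assay, mg.
    assay_volume : float
        Total assay volume, uL.
    external_conc : float
        External substrate concentration, mM.
    specific_activity : float, optional
        Radiolabel specific activity, mCi/mmol.
    counting_efficiency : float, optional
        Scintillation counting efficiency, fraction in (0, 1].
    protein_mass : float, optional
        Reconstituted protein in the assay, ug.
    """

    lipid_mass: float
    assay_volume: float
    external_conc: float
    specific_activity: Optional[float] = None
    counting_efficiency: Optional[float] = None
    protein_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lipid_mass < 0:
            raise GeometryError(f"lipid mass must be >= 0, got {self.lipid_mass}")
        if self.assay_volume <= 0:
            raise GeometryError(f"assay volume must be > 0, got {self.assay_volume}")
        if self.external_conc < 0:
            raise GeometryError(f"external concentration must be >= 0, got {self.external_conc}")
        if self.counting_efficiency is not None and not (0 < self.counting_efficiency <= 1):
            raise GeometryError(
                f"counting efficiency must be in (0, 1], got {self.counting_efficiency}"
            )
        if self.protein_mass is not None and self.protein_mass <= 0:
            raise GeometryError(f"protein mass must be > 0, got {self.protein_mass}")


@dataclass(frozen=True)
class GeometryResult:
    """All intermediates of the internal-volume chain for one assay."""

    n_lipids_per_liposome: float   # lipids / vesicle
    lipid_conc: float              # mol/L
    n_liposomes_per_L: float       # vesicles / L
    n_liposomes_in_assay: float    # vesicles in the assay volume
    v_internal: float              # L
    v_internal_uL: float           # uL

    def as_dict(self) -> dict:
        return {
            "n_lipids_per_liposome": {"value": self.n_lipids_per_liposome, "unit": "lipids/liposome"},
            "lipid_conc": {"value": self.lipid_conc, "unit": "mol/L"},
            "n_liposomes_per_L": {"value": self.n_liposomes_per_L, "unit": "1/L"},
            "n_liposomes_in_assay": {"value": self.n_liposomes_in_assay, "unit": "count"},
            "v_internal": {"value": self.v_internal, "unit": "L"},
            "v_internal_uL": {"value": self.v_internal_uL, "unit": "uL"},
        }


def lipids_per_liposome(spec: LiposomeSpec) -> float:
    """Total lipids per vesicle: both monolayer areas over the headgroup area.

    N_totPL = (4*pi*r^2 + 4*pi*(r-m)^2) / a, counting the outer leaflet at
    the outer radius and the inner leaflet at the inner radius.
    """
    outer = 4.0 * math.pi * spec.r_outer**2
    inner = 4.0 * math.pi * spec.r_inner**2
    return (outer + inner) / spec.a_headgroup


def lipid_molar_concentration(assay: AssaySpec, spec: LiposomeSpec) -> float:
    """Lipid molarity in the assay (mol/L) from lipid mass and volume."""
    g_per_L = assay.lipid_mass / assay.assay_volume * MG_PER_UL_TO_G_PER_L
    return g_per_L / spec.lipid_mw


def liposome_count(assay: AssaySpec, spec: LiposomeSpec) -> tuple[float, float]:
    """Vesicle number per litre and in the assay volume.

    N_PL/L = c_lipid * N_A / N_totPL. Returns (per litre, per assay).
    """
    per_liter = lipid_molar_concentration(assay, spec) * AVOGADRO / lipids_per_liposome(spec)
    in_assay = per_liter * assay.assay_volume * UL_TO_L
    return per_liter, in_assay


def internal_volume(assay: AssaySpec, spec: LiposomeSpec) -> GeometryResult:
    """Full geometry chain ending in the total intraliposomal volume V_PL.

    V_PL = (4/3)*pi*(r-m)^3 * N_PL, with N_PL the vesicle count in the
    assay and r-m the inner radius.
    """
    n_tot = lipids_per_liposome(spec)
    conc = lipid_molar_concentration(assay, spec)
    per_liter, in_assay = liposome_count(assay, spec)
    v_one = (4.0 / 3.0) * math.pi * spec.r_inner**3 * NM3_TO_L  # L per vesicle
    v_internal = v_one * in_assay
    return GeometryResult(
        n_lipids_per_liposome=n_tot,
        lipid_conc=conc,
        n_liposomes_per_L=per_liter,
        n_liposomes_in_assay=in_assay,
        v_internal=v_internal,
        v_internal_uL=v_internal / UL_TO_L,
    )
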