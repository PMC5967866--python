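"""Vesicle geometry chain and channel-vs-transporter phenotype call.

Builds the benchmark flux assay (100-nm vesicles, 4 uL of 5 mg/mL
proteoliposomes in 100 uL, 0.5 mM external sulfate), derives the total
intraliposomal volume, converts the measured peak (0.1869 nmol) and
plateau (0.1145 nmol) uptake into internal concentrations and fold
accumulations, and classifies the transport mode.
"""

from vesiflux import (
    AssaySpec,
    LiposomeSpec,
    classify_phenotype,
    internal_concentration,
    internal_volume,
)

liposome = LiposomeSpec(r_outer=50.0, m_membrane=4.0, a_headgroup=0.7, lipid_mw=790.85)
assay = AssaySpec(lipid_mass=0.02, assay_volume=100.0, external_conc=0.5)

geom = internal_volume(assay, liposome)
print(f"lipids per vesicle      {geom.n_lipids_per_liposome:,.2f}")
print(f"lipid concentration     {geom.lipid_conc:.3e} mol/L")
print(f"vesicles per liter      {geom.n_liposomes_per_L:.3e}")
print(f"internal volume         {geom.v_internal_uL:.4f} uL")

c_peak = internal_concentration(0.1869e-9, geom.v_internal)
c_plateau = internal_concentration(0.1145e-9, geom.v_internal)
report = classify_phenotype(c_peak, c_plateau, assay.external_conc)
print(f"internal conc (peak)    {c_peak:.3f} mM")
print(f"internal conc (plateau) {c_plateau:.3f} mM")
print(f"fold accumulation       {report.fold_peak:.2f} (peak), {report.fold_plateau:.2f} (plateau)")
print(f"phenotype call          {report.call}")

# A fold accumulation of ~5 at the peak and ~3 at the plateau is far below
# the concentrative regime (>= 50-fold): the protein equilibrates its
# substrate rather than pumping it, i.e. it behaves like a channel.
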