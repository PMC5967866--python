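# vesiflux

Quantitative analysis of membrane-transport assays in reconstituted
proteoliposomes. The package answers the question a flux assay is designed
to ask — *does this protein pump its substrate, or merely let it through?* —
by converting measured radiotracer uptake into intraliposomal
concentrations and fold-accumulation statistics, and it carries the
supporting computations a transport study needs: Michaelis–Menten kinetics
with turnover numbers, EC50/IC50 binding isotherms, Nernst diffusion
potentials and single-channel conductance fits. A seeded synthetic-data
module generates assay-shaped datasets for every stage, so the whole
pipeline is testable without measured data.

It is written for membrane biophysicists and biochemists who run
proteoliposome uptake assays, scintillation-proximity binding experiments
or planar-bilayer recordings and want the downstream arithmetic to be
reproducible, unit-checked code instead of a spreadsheet.

## The model

For monodisperse unilamellar vesicles of outer radius *r*, bilayer
thickness *m*, headgroup area *a* and average lipid molar mass *M*:

```
N_totPL = [4πr² + 4π(r−m)²] / a                lipids per vesicle
c_lipid = (lipid mass / assay volume) / M       mol/L
N_PL    = c_lipid · N_A / N_totPL               vesicles per litre
V_PL    = (4/3)π(r−m)³ · N_PL(assay)            total internal volume
```

An accumulated amount *n* (mol) then gives the internal concentration
`c_in = n / V_PL` and the fold accumulation `c_in / c_out`. Passive
(channel-like, uniport) flux equilibrates at fold ≈ 1 for an uncharged
solute with no potential; ion-coupled (symport) transport concentrates
substrate to `fold ≫ 1`, bounded by the driving ion's electrochemical
gradient. The classifier calls fold ≤ 10 channel-like and fold ≥ 50
concentrative by default (both thresholds configurable, always reported).

Around this core: `v = Vmax·S/(Km+S)` saturation kinetics with
`kcat = Vmax·M/60000`, four-parameter log-logistic displacement fits,
`E = (RT/zF)·ln([X]out/[X]in)` diffusion potentials and ohmic I–V slope
conductances.

## Worked example

```python
from vesiflux import (AssaySpec, LiposomeSpec, classify_phenotype,
                      internal_concentration, internal_volume)

liposome = LiposomeSpec(r_outer=50.0, m_membrane=4.0, a_headgroup=0.7, lipid_mw=790.85)
assay = AssaySpec(lipid_mass=0.02, assay_volume=100.0, external_conc=0.5)

geom = internal_volume(assay, liposome)
c_peak = internal_concentration(0.1869e-9, geom.v_internal)
c_plateau = internal_concentration(0.1145e-9, geom.v_internal)
report = classify_phenotype(c_peak, c_plateau, assay.external_conc)
```

Running `python examples/worked_geometry_and_phenotype.py` prints:

```
lipids per vesicle      82,866.24
lipid concentration     2.529e-04 mol/L
vesicles per liter      1.838e+15
internal volume         0.0749 uL
internal conc (peak)    2.494 mM
internal conc (plateau) 1.528 mM
fold accumulation       4.99 (peak), 3.06 (plateau)
phenotype call          channel-like
```

A 100-nm vesicle holds ~82,866 lipids; 0.02 mg of lipid in 100 µL makes
1.8 × 10¹¹ vesicles enclosing 0.0749 µL of internal water. The measured
0.1869 nmol peak uptake therefore corresponds to 2.49 mM inside — only
~5-fold above the 0.5 mM external sulfate, and ~3-fold at the plateau:
equilibrative, channel-like flux, not concentrative transport.

The other scripts in `examples/` demonstrate the kinetics, binding,
electrophysiology and synthetic-pipeline capabilities, each printing the
fitted parameters and a line on what they mean.

## Command line

The same stages are exposed as a thin CLI:

```
vesiflux geometry --config assay.yaml
vesiflux accumulate uptake.csv --config assay.yaml
vesiflux fit-mm rates.csv --protomer-mass 27729
vesiflux fit-displace spa.csv --mode heterologous_inhibition
vesiflux nernst --k-in 1 --k-out 100
vesiflux fit-iv iv.csv
vesiflux simulate mm --seed 1 --out rates.csv
```

CSV schemas and the YAML/TOML config format are documented in
`src/vesiflux/io.py` and `docs/methods.md`.

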