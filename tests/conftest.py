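import numpy as np
import pytest

from vesiflux import AssaySpec, LiposomeSpec, internal_volume

# Benchmark assay: 100-nm extruded vesicles, 4-nm bilayer, 0.7-nm^2
# headgroups, E. coli polar lipid average MW, 4 uL of 5 mg/mL vesicles in
# a 100-uL reaction with 0.5 mM external sulfate.


@pytest.fixture(scope="session")
def bench_liposome() -> LiposomeSpec:
    return LiposomeSpec(r_outer=50.0, m_membrane=4.0, a_headgroup=0.7, lipid_mw=790.85)


@pytest.fixture(scope="session")
def bench_assay() -> AssaySpec:
    return AssaySpec(
        lipid_mass=0.02,
        assay_volume=100.0,
        external_conc=0.5,
        specific_activity=50.0,
        counting_efficiency=0.9,
        protein_mass=1.0,
    )


@pytest.fixture(scope="session")
def bench_v_internal(bench_assay, bench_liposome) -> float:
    return internal_volume(bench_assay, bench_liposome).v_internal
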