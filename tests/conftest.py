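import numpy as np
import pandas as pd
import pytest

from tissuelight import invert, io, mc, penetration


@pytest.fixture(scope="session")
def reference_table():
    return io.load_reference_table()


@pytest.fixture(scope="session")
def reference_depths(reference_table):
    """Mean-property depth spectrum per reference tissue."""
    out = {}
    for tissue in io.REFERENCE_TISSUES:
        t = reference_table[reference_table.tissue == tissue]
        out[tissue] = penetration.depth_spectrum(
            t[["wavelength_nm", "mu_a", "mu_sp"]], aggregate="mean_properties"
        )
    return out


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-budget solver configuration for unit tests."""
    return invert.SolverConfig(
        lut_shape=(6, 6),
        lut_n_photons=20_000,
        n_photons_iter=30_000,
        n_photons_final=50_000,
        max_iter=40,
    )


@pytest.fixture(scope="session")
def lut_d12(small_cfg):
    """Shared lookup table for 1.2 mm samples at default (g, n)."""
    return invert.build_lookup(1.2, cfg=small_cfg)


@pytest.fixture(scope="session")
def ureter_635_measurement():
    """A high-fidelity forward measurement at the reference human-ureter
    635 nm optical properties (mu_a = 0.25, mu_sp = 1.71, d = 1.2 mm)."""
    stack = mc.build_slab(0.25, 1.71, 1.2)
    res = mc.simulate_rt(stack, n_photons=500_000, seed=42)
    return res
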