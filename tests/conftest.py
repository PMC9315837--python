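import numpy as np
import pytest

import memchrom as mc


@pytest.fixture(scope="session")
def disc_column() -> mc.MembraneColumn:
    """Commercial-membrane disc: 275 um thick, 2.2 cm diameter, 80% porosity."""
    return mc.MembraneColumn.from_disc(thickness=275e-4, diameter=2.2, void_fraction=0.8)


@pytest.fixture(scope="session")
def conditions_1ml() -> mc.OperatingConditions:
    return mc.OperatingConditions.ml_per_min(1.0)


@pytest.fixture(scope="session")
def psd_narrow() -> mc.PoreSizeDistribution:
    """Gaussian PSD mu=1.5 um, sigma=0.10 um on the catalogue 0.5-6.5 um range."""
    return mc.PoreSizeDistribution.from_microns(1.5, 0.10, 0.5, 6.5)


@pytest.fixture(scope="session")
def make_psd():
    def _make(sigma_um: float, r_max_um: float = 6.5, **kw) -> mc.PoreSizeDistribution:
        return mc.PoreSizeDistribution.from_microns(1.5, sigma_um, 0.5, r_max_um, **kw)

    return _make


@pytest.fixture(scope="session")
def bundle_narrow(psd_narrow, disc_column, conditions_1ml) -> mc.PoreBundle:
    return mc.PoreBundle(psd_narrow, disc_column, conditions_1ml)


@pytest.fixture(scope="session")
def bench_column() -> mc.MembraneColumn:
    """Five-layer affinity stack: L = 0.1 cm, A = 3.8 cm^2, eps = 0.545."""
    return mc.MembraneColumn(thickness=0.1, area=3.8, void_fraction=0.545, n_layers=5)


@pytest.fixture(scope="session")
def bench_isotherm() -> mc.BiLangmuir:
    """Two-site isotherm: irreversible (K_d = 0) plus reversible binding."""
    return mc.BiLangmuir(q_m_irr=4.75, k_d_irr=0.0, q_m_rev=7.00, k_d_rev=1.15)


@pytest.fixture(scope="session")
def bench_extra_column() -> mc.ExtraColumnConfig:
    return mc.ExtraColumnConfig(v_cstr=0.69, v_pfr_intercept=1.753, v_pfr_slope=0.025)


@pytest.fixture(scope="session")
def bench_config(bench_column, bench_isotherm, bench_extra_column) -> mc.SimulationConfig:
    """Full frontal-capture configuration: F = 1 mL/min, c0 = 0.48 mg/mL,
    measured dispersivity 0.104 cm."""
    return mc.SimulationConfig(
        column=bench_column,
        conditions=mc.OperatingConditions.ml_per_min(1.0, 0.48),
        isotherm=bench_isotherm,
        extra_column=bench_extra_column,
        dispersivity=0.104,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
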