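import numpy as np
import pytest

from cvpheno import RunConfig, SuspensionModel, VoltageProgram


@pytest.fixture(scope="session")
def paper_program() -> VoltageProgram:
    """The study acquisition program: −0.9→0.9 V, 2 mV steps, 0.04 V/s."""
    return VoltageProgram(v_min=-0.9, v_max=0.9, e_step=0.002, s_rate=0.04)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def pure_capacitor(c_tot: float, **overrides) -> SuspensionModel:
    """Noise-free, peak-free, resistance-free model with C_tot = c_media."""
    defaults = dict(c_media=c_tot, n_cells=0, r_series=0.0,
                    faradaic_peak_i=0.0, noise_sd=0.0)
    defaults.update(overrides)
    return SuspensionModel(**defaults)


def small_run_config(seed: int, **overrides) -> RunConfig:
    """Study-conditions config scaled down for repeated seeded runs."""
    defaults = dict(
        seed=seed,
        concentrations=(10, 100, 1_000),
        cells_per_type_imaged=25,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)
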