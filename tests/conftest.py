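import numpy as np
import pytest

from ddmcn import (
    CalibrationCurve,
    DuplexSimConfig,
    PunctaSimConfig,
    simulate_duplex_droplets,
    simulate_puncta_cells,
)


@pytest.fixture
def ba_curve() -> CalibrationCurve:
    """Calibration curve for the 69-bp beta-actin assay (k from Eq-style model)."""
    return CalibrationCurve(plateau=30000.0, k=(69.0 / (1235.0 * 1.06)) ** 2)


@pytest.fixture
def duplex_well():
    """One well-separated simulated duplex well with truth labels."""
    cfg = DuplexSimConfig(conc_a=2700.0, conc_b=20.0, seed=7)
    table, labels, truth = simulate_duplex_droplets(cfg)
    return cfg, table, labels, truth


@pytest.fixture
def puncta_batch():
    """A default-condition imaging batch with per-cell true genome counts."""
    cfg = PunctaSimConfig(seed=11)
    cells, truth = simulate_puncta_cells(cfg)
    return cfg, cells, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
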