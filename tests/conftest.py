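import numpy as np
import pandas as pd
import pytest

from plasmidkinetics import ExposureAxis, GelDataset, InitialState, species_proportions
from plasmidkinetics.dataset import GEL_TABLE_COLUMNS

# (ksr, krl) pairs spanning the fitted dose-axis and time-axis regimes of
# the assay: fast EBRT conversion at low plasmid concentration, slow at
# high concentration, and the radionuclide incubation rates.
RATE_PAIRS = [
    (1.21, 0.017),
    (0.45, 0.004),
    (0.59, 0.02),
    (0.159, 0.002),
    (0.131, 0.001),
]

EBRT_GRID = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0]
TIME_GRID = [0.0, 2.0, 4.0, 21.0, 25.0]


def make_noiseless_dataset(
    ksr: float,
    krl: float,
    s0: float = 0.97,
    grid=EBRT_GRID,
    axis: ExposureAxis = ExposureAxis.DOSE,
    n_replicates: int = 1,
    condition: str = "noiseless",
) -> GelDataset:
    """Exact model predictions packed as a replicate table (percent scale)."""
    s, r, lin = species_proportions(grid, ksr, krl, InitialState(s0))
    rows = []
    for x, si, ri, li in zip(grid, s, r, lin):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "condition": condition,
                    "axis_kind": axis.value,
                    "x": x,
                    "replicate": rep,
                    "pct_supercoiled": 100 * si,
                    "pct_relaxed": 100 * ri,
                    "pct_linear": 100 * li,
                }
            )
    table = pd.DataFrame(rows, columns=GEL_TABLE_COLUMNS)
    return GelDataset(table=table, axis=axis, condition=condition)


@pytest.fixture
def ebrt_noiseless() -> GelDataset:
    return make_noiseless_dataset(1.21, 0.017)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
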