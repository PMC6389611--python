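import numpy as np
import pandas as pd
import pytest

from telostat.data_model import build_measurement_grid


def grid_table(sample_values: dict[str, list], n_metaphases: int = 10) -> pd.DataFrame:
    """Raw intensity table in the four-index-column layout, one column per
    sample; values align with the lexicographic measurement grid."""
    grid = build_measurement_grid(n_metaphases)
    frame = pd.DataFrame(
        {
            "Chromosome": [f"Chr{c:02d}" for c, _, _, _ in grid],
            "1o2o": [h for _, h, _, _ in grid],
            "Metaphase": [m for _, _, m, _ in grid],
            "Tails": [e for _, _, _, e in grid],
        }
    )
    for code, values in sample_values.items():
        assert len(values) == len(grid)
        frame[code] = values
    return frame


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
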