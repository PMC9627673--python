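import numpy as np
import pandas as pd
import pytest

from metabotype.iontable import IonTable
from metabotype.synthetic_data import (
    generate_cell_line_screen,
    generate_flux_metabolite_panel,
)


def make_table(values, batch=None, cell_line=None, injection_order=None,
               is_qc=None, confluency=0.7, formulas=None, mz=None):
    """Build a small IonTable from a 2-D array with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = [f"s{i}" for i in range(n)]
    ion_ids = [f"ion{j}" for j in range(m)]
    samples = pd.DataFrame(
        {
            "cell_line": cell_line if cell_line is not None else [f"L{i}" for i in range(n)],
            "batch": batch if batch is not None else 1,
            "injection_order": injection_order if injection_order is not None
            else np.arange(n, dtype=float) * 5.0,
            "confluency": confluency,
            "is_qc": is_qc if is_qc is not None else False,
            "replicate": 0,
        },
        index=sample_ids,
    )
    ions = pd.DataFrame(
        {
            "mz": mz if mz is not None else 100.0 + np.arange(m, dtype=float),
            "formulas": formulas if formulas is not None else [f"F{j}" for j in range(m)],
        },
        index=ion_ids,
    )
    return IonTable(pd.DataFrame(values, index=sample_ids, columns=ion_ids), samples, ions)


@pytest.fixture(scope="session")
def small_screen():
    """Artifact-bearing screen, small enough for fast unit tests."""
    table, truth = generate_cell_line_screen(
        n_lines=60, n_batches=4, n_ions=120, n_replicates=3,
        qc_replicates_per_batch=6, seed=11,
    )
    return table, truth


@pytest.fixture(scope="session")
def clean_screen():
    """Screen with all acquisition artifacts switched off."""
    table, truth = generate_cell_line_screen(
        n_lines=60, n_batches=4, n_ions=120, n_replicates=3,
        qc_replicates_per_batch=4, seed=7,
        batch_effect_range=(1.0, 1.0), batch_ion_sd=0.0,
        drift_amplitude=1.0, size_factor_sd=0.0,
    )
    return table, truth


@pytest.fixture(scope="session")
def flux_panel():
    return generate_flux_metabolite_panel(seed=5)
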