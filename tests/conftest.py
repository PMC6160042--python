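import numpy as np
import pytest

from faimspipe.io import FAIMSRun, FeatureTable, IonMatrix
from faimspipe.simulate import SynthSpec, generate_cohort


@pytest.fixture
def toy_run() -> FAIMSRun:
    """2x2-per-polarity run with values 1..8 in linearisation order."""
    return FAIMSRun(
        "toy",
        1,
        IonMatrix("positive", [[1.0, 2.0], [3.0, 4.0]]),
        IonMatrix("negative", [[5.0, 6.0], [7.0, 8.0]]),
    )


def random_run(rng: np.random.Generator, rows: int = 8, cols: int = 4,
               sample_id: str = "S1", run_index: int = 1) -> FAIMSRun:
    return FAIMSRun(
        sample_id,
        run_index,
        IonMatrix("positive", rng.normal(size=(rows, cols))),
        IonMatrix("negative", rng.normal(size=(rows, cols))),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort on a 64x16 grid: fast but structured."""
    spec = SynthSpec(n_case=15, n_control=15, rows=64, cols=16, seed=7)
    runs, records = generate_cohort(spec)
    return spec, runs, records


def table_from(values, prefix="f", provenance="raw") -> FeatureTable:
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        [f"s{i}" for i in range(values.shape[0])],
        [f"{prefix}{j}" for j in range(values.shape[1])],
        values,
        provenance,
    )
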