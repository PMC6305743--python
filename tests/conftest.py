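import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfdeff import AssayRecord, SimulationConfig, simulate_grouped_assay

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_by_two_records():
    """Balanced 2 patients x 2 treatments x 2 replicates worked example.

    Hand decomposition: SS_total 22 = SS_treatment 18 + SS_patient 2 +
    SS_interaction 2 + SS_residual 0.
    """
    layout = {"P1": {"vehicle": (1, 1), "corrector": (3, 3)},
              "P2": {"vehicle": (1, 1), "corrector": (5, 5)}}
    records = []
    for patient, arms in layout.items():
        for treatment, values in arms.items():
            for i, v in enumerate(values):
                records.append(
                    AssayRecord(patient, f"{patient}-A1", treatment, f"r{i}", float(v))
                )
    return records


@pytest.fixture
def grouped_sim_records():
    """One calibrated grouped-assay dataset (23 aliquots, sizes 3-9)."""
    return simulate_grouped_assay(SimulationConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
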