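import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ctcpredict import SimulationConfig, generate_cohort
from ctcpredict.datatypes import (
    ROLE_EPITHELIAL,
    ROLE_REFERENCE,
    ROLE_TARGET,
    CtMatrix,
)
from ctcpredict import qc as qc_mod

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_ct(ct_values: dict[str, list], roles: dict[str, str]) -> CtMatrix:
    """Tiny hand-built Ct matrix; lists are per-sample values, NaN = undetected."""
    genes = list(ct_values)
    n = len(next(iter(ct_values.values())))
    samples = [f"P{i}" for i in range(1, n + 1)]
    frame = pd.DataFrame(
        [ct_values[g] for g in genes], index=genes, columns=samples, dtype=float
    )
    return CtMatrix(frame, pd.Series(roles))


@pytest.fixture(scope="session")
def planted_cohort():
    """A 45-sample cohort with a strong planted effect, QC'd and filtered."""
    cohort = generate_cohort(SimulationConfig(seed=11, effect_size=3.0))
    retained, _ = qc_mod.apply_qc(cohort.ct)
    expr = qc_mod.delta_ct_normalize(retained)
    filtered = qc_mod.variance_filter(expr)
    labels = cohort.truth_labels.loc[filtered.samples]
    return cohort, filtered, labels


@pytest.fixture()
def tiny_ct():
    """3 reference + 2 epithelial + 3 target genes, 3 samples."""
    return make_ct(
        {
            "HMBS": [20.0, 24.0, 27.0],
            "HPRT1": [22.0, np.nan, 27.0],
            "GUSB": [24.0, 28.0, 27.0],
            "EPI1": [30.0, np.nan, np.nan],
            "EPI2": [31.0, np.nan, np.nan],
            "T1": [25.0, 26.0, 30.0],
            "T2": [22.0, 30.0, 31.0],
            "T3": [np.nan, 28.0, 33.0],
        },
        {
            "HMBS": ROLE_REFERENCE,
            "HPRT1": ROLE_REFERENCE,
            "GUSB": ROLE_REFERENCE,
            "EPI1": ROLE_EPITHELIAL,
            "EPI2": ROLE_EPITHELIAL,
            "T1": ROLE_TARGET,
            "T2": ROLE_TARGET,
            "T3": ROLE_TARGET,
        },
    )
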