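import numpy as np
import pandas as pd
import pytest

from devoxel.asl_cbf import AslAcquisition
from devoxel.regional_analysis import CohortTable
from devoxel.synthetic_phantom import PhantomSpec, make_phantom_anatomy


@pytest.fixture
def acq():
    """Default acquisition parameters (17-slice protocol)."""
    return AslAcquisition()


@pytest.fixture
def small_spec():
    return PhantomSpec(shape=(16, 18, 6), n_pairs=8, seed=7)


@pytest.fixture
def small_anatomy(small_spec):
    return make_phantom_anatomy(small_spec)


def make_study_cohort():
    """47 T2DM + 41 controls with the printed exclusion cascade.

    CBF-stage exclusions: 6 T2DM (claustrophobia x2, parkinsonism x1,
    brain injury x1, incidental finding x1, ASL artifact x1) and 2
    controls (impaired fasting glucose); flow stage additionally excludes
    5 T2DM and 2 controls with no ECG signal.
    """
    rows = []
    t2dm_cbf_reasons = (
        ["cbf:claustrophobia"] * 2
        + ["cbf:parkinsonism", "cbf:brain_injury", "cbf:incidental_finding",
           "cbf:asl_artifact"]
    )
    for i in range(47):
        reasons = []
        if i < len(t2dm_cbf_reasons):
            reasons.append(t2dm_cbf_reasons[i])
        elif i < len(t2dm_cbf_reasons) + 5:
            reasons.append("flow:no_ecg")
        rows.append({"id": f"t2d{i:03d}", "group_t2dm": True,
                     "exclusion_reasons": ";".join(reasons)})
    for i in range(41):
        reasons = []
        if i < 2:
            reasons.append("cbf:impaired_fasting_glucose")
        elif i < 4:
            reasons.append("flow:no_ecg")
        rows.append({"id": f"ctl{i:03d}", "group_t2dm": False,
                     "exclusion_reasons": ";".join(reasons)})
    return CohortTable(pd.DataFrame(rows))


@pytest.fixture
def study_cohort():
    return make_study_cohort()
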