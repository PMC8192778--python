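import numpy as np
import pandas as pd
import pytest

from rrbdyn.nii import COGNITIVE_CIRCUIT, MOTOR_CIRCUIT, windowed_nii
from rrbdyn.simulate import CohortSpec, simulate_cohorts
from rrbdyn.windows import make_taper, sliding_window_connectivity


def windowed_mean_features(cohort, step: int = 1) -> pd.DataFrame:
    """Per-subject windowed NII summaries (mean/SD CNII, mean MNII)."""
    kern = make_taper(cohort.spec.analysis_window_samples)
    rows = {}
    for ts in cohort.timeseries:
        wc = sliding_window_connectivity(ts, kern, step)
        c = windowed_nii(wc, COGNITIVE_CIRCUIT)
        m = windowed_nii(wc, MOTOR_CIRCUIT)
        rows[ts.subject_id] = {
            "cnii_mean": float(c.mean()),
            "cnii_sd": float(c.std(ddof=1)),
            "mnii_mean": float(m.mean()),
        }
    feats = pd.DataFrame.from_dict(rows, orient="index")
    feats.index.name = "subject_id"
    return feats


def group_values(cohort, feats: pd.DataFrame, column: str):
    groups = cohort.manifest.set_index("subject_id")["group"]
    v = feats[column]
    return (v[groups.loc[v.index] == "ASD"].to_numpy(),
            v[groups.loc[v.index] == "TD"].to_numpy())


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort reused by I/O and pipeline tests."""
    spec = CohortSpec(n_per_group=10, n_timepoints=160, seed=42)
    return simulate_cohorts(spec)


@pytest.fixture(scope="session")
def cohort_on_disk(small_cohort, tmp_path_factory):
    from rrbdyn.io import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    manifest_path, ts_dir = write_cohort(small_cohort, out)
    return {"manifest": manifest_path, "timeseries": ts_dir, "root": out,
            "cohort": small_cohort}
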