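import numpy as np
import pandas as pd
import pytest

import tilscape as ts


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by the integration tests."""
    out = tmp_path_factory.mktemp("pipe") / "run"
    cfg = ts.PipelineConfig(
        out_dir=str(out),
        seed=7,
        n_patients=14,
        map_height=110,
        map_width=110,
        fragment_radius=16.0,
        ap_max_points=400,
        min_patients=8,
    )
    artifacts = ts.run_pipeline(cfg)
    return cfg, artifacts


def make_roi(grid, scale="binary", roi_index=0, map_id="m0"):
    return ts.ROI(
        grid=np.asarray(grid, dtype=float),
        offset=(0, 0),
        parent_map_id=map_id,
        roi_index=roi_index,
        scale=scale,
    )


@pytest.fixture
def roi_factory():
    return make_roi


def make_survival_frame(n, seed, beta, threshold_effect=False, driver_noise_on_pct=None):
    """Cohort frame with the columns fit_cox expects; measure column 'm'."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    meas = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)], "m": x})
    if driver_noise_on_pct is not None:
        meas["pct_tils"] = x
        meas["m"] = x + rng.normal(0, driver_noise_on_pct, n)
        driver = "pct_tils"
    else:
        meas["pct_tils"] = rng.uniform(0, 1, n)
        driver = "m"
    spec = ts.CohortSpec(
        n_patients=n,
        driver_measure=driver,
        beta=beta,
        threshold_effect=threshold_effect,
        threshold=0.5,
        seed=seed,
    )
    clin = ts.generate_cohort(spec, meas)
    df = meas.merge(clin, on="patient_id")
    df["cancer_type"] = "sim"
    df["scale"] = "binary"
    return df


@pytest.fixture
def survival_frame_factory():
    return make_survival_frame
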