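import numpy as np
import pandas as pd
import pytest

from phistress.pipeline import (
    PhiSeries,
    WindowingPlan,
    aggregate_main_complex_z,
    compute_phi_series,
    zscore_log_phi,
)
from phistress.synthetic import SyntheticSpec, generate_recording

#: reduced-profile windowing used throughout the suite (10 s / 5 s at 50 fps)
REDUCED_PLAN = WindowingPlan(td_frames=500, shift_frames=250)
REDUCED_PRE_END = 60.0
REDUCED_TASK = (60.0, 240.0)


@pytest.fixture(scope="session")
def reduced_spec():
    return SyntheticSpec.reduced()


@pytest.fixture(scope="session")
def moderate_recording(reduced_spec):
    return generate_recording(reduced_spec, "Moderate", seed=101)


@pytest.fixture(scope="session")
def processed_series(moderate_recording):
    """One fully processed reduced-scale series (shared; treat as read-only)."""
    s = compute_phi_series(moderate_recording, REDUCED_PLAN, tau=1)
    s = zscore_log_phi(s, pre_task_end_s=REDUCED_PRE_END, guard_windows=2)
    return aggregate_main_complex_z(s)


def make_series_stub(sum_z, spacing_s=5.0, t0=5.0, channels=("a", "b")):
    """A minimal PhiSeries carrying only the fields the score layer reads."""
    sum_z = np.asarray(sum_z, dtype=float)
    n = len(sum_z)
    times = t0 + spacing_s * np.arange(n)
    return PhiSeries(
        channels=tuple(channels),
        tau=1,
        plan=WindowingPlan(2, 1),
        fps=1.0,
        window_times=times,
        phi_mip=np.ones(n),
        mip_cut=["a"] * n,
        mip_partition=[None] * n,
        main_complexes=[("a+b",)] * n,
        subset_phi=pd.DataFrame({"a+b": np.ones(n)}),
        subset_mip_cut=pd.DataFrame({"a+b": ["a"] * n}),
        padded=np.zeros(n, dtype=bool),
        missing=~np.isfinite(sum_z),
        z_log_phi=sum_z.copy(),
        z_subsets=pd.DataFrame({"a+b": sum_z}),
        sum_z=sum_z.copy(),
        max_z=sum_z.copy(),
    )
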