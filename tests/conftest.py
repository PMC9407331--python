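import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from citrusnmr import (
    BENCHTOP_SCHEME,
    HIGH_FIELD_SCHEME,
    AcquisitionScheme,
    ExtractComposition,
    ProcessingParams,
    synthesize_fid,
)
from citrusnmr.simulate import composition_for_ratio, default_citrate_offset
from citrusnmr.types import Singlet, SpinSignal


@pytest.fixture(scope="session")
def small_scheme() -> AcquisitionScheme:
    """Short high-field acquisition for fast unit tests (the production
    schemes use 32 K points; behaviour under test is length-agnostic)."""
    return AcquisitionScheme(
        spectrometer_frequency=400.13,
        spectral_width=8000.0,
        n_points=4096,
        n_scans=1,
        flip_angle=90.0,
    )


@pytest.fixture(scope="session")
def fast_params() -> ProcessingParams:
    """Deterministic low-cost processing for synthetic FIDs of known
    (zero) phase and flat baseline."""
    return ProcessingParams(
        zero_fill_to=8192,
        phase_mode=("fixed", 0.0, 0.0),
        baseline_mode="none",
        alignment="none",
    )


@pytest.fixture(scope="session")
def default_composition() -> ExtractComposition:
    comp = composition_for_ratio(9.31)
    return dataclasses.replace(
        comp,
        shift_jitter_scale=0.0,
        citrate_center_offset=default_citrate_offset(HIGH_FIELD_SCHEME),
    )


@pytest.fixture(scope="session")
def singlet_fid(small_scheme):
    """Noise-free single sucrose singlet at 5.40 ppm."""
    comp = ExtractComposition(
        sucrose=10.0, glucose_total=0.0, fructose_total=0.0, citric_acid=0.0,
        shift_jitter_scale=0.0,
    )
    line = [SpinSignal("sucrose", 5.40, Singlet(), 1)]
    return synthesize_fid(comp, small_scheme, line_list=line, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def variety_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variety_id": ["V1", "V2", "V3", "V4", "V5"],
            "target_ratio": [9.31, 10.12, 7.70, 6.34, 4.16],
        }
    )


TABLE1_ACCEPTABILITY = np.array([7.4, 6.9, 5.5, 4.8, 3.6])
TABLE1_RATIO_400 = np.array([9.31, 10.12, 7.70, 6.34, 4.16])
TABLE1_RATIO_60 = np.array([10.85, 11.53, 8.45, 6.75, 3.88])
TABLE1_VARIETIES = ["B475B", "F7P3", "B475A", "B79", "M16"]
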