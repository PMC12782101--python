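"""Shared fixtures: small atlases and seeded synthetic cohorts."""

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pytest

from cvrkit import CohortConfig, generate_cohort
from cvrkit.atlas import DEFAULT_ATLAS

#: Reduced atlas for search tests: the disease-signal regions (ventricular
#: expansion + limbic atrophy, all AB-dependent under the default generator)
#: plus neutral noisy regions.
PLANTED_REGIONS = (
    "lateral_ventricle",
    "hippocampus",
    "entorhinal",
    "amygdala",
    "thalamus",
    "caudate",
    "putamen",
    "precuneus",
    "cuneus",
    "lingual",
    "fusiform",
    "insula",
)


@pytest.fixture(scope="session")
def small_atlas():
    return DEFAULT_ATLAS.subset(PLANTED_REGIONS)


@pytest.fixture(scope="session")
def two_region_atlas():
    return DEFAULT_ATLAS.subset(("hippocampus", "lateral_ventricle"))


@pytest.fixture(scope="session")
def planted_table(small_atlas):
    """300-subject cohort on the reduced atlas with the default planted
    disease signal (AB-dependent ventricular expansion and limbic atrophy)."""
    return generate_cohort(CohortConfig(n_subjects=300, seed=7), small_atlas)


@pytest.fixture(scope="session")
def medium_table(two_region_atlas):
    """250-subject two-region cohort used for model-level tests."""
    return generate_cohort(CohortConfig(n_subjects=250, seed=21), two_region_atlas)


@pytest.fixture(scope="session")
def hv_series(medium_table):
    from cvrkit import column_ratio

    return column_ratio(medium_table, "hippocampus", "icv", "hippocampus_icv")


@dataclass
class StubFit:
    """Minimal stand-in (synthetic) for AtrophyLMMResults in closed-form
    metric tests: carries exactly the fields the trial metrics read."""

    slope: float = -0.02
    var_b1: float = 1e-5
    sigma: float = 0.04
    resid_sd: float | None = None
    n_resid: int = 200
    t_ab: float = 2.0
    t_dx: float = 1.0
    converged: bool = True

    params: pd.Series = field(init=False)
    bse: pd.Series = field(init=False)
    tvalues: pd.Series = field(init=False)

    def __post_init__(self):
        idx = ["intercept", "age_bl", "sex", "time", "time:DX", "time:AB",
               "time:APOE4"]
        self.params = pd.Series(
            [0.0, 0.0, 0.0, self.slope, 0.0, 0.0, 0.0], index=idx
        )
        self.bse = pd.Series(1.0, index=idx)
        self.tvalues = pd.Series(
            [0.0, 0.0, 0.0, 0.0, self.t_dx, self.t_ab, 0.0], index=idx
        )

    @property
    def var_slope_re(self):
        return self.var_b1

    @property
    def sigma_e(self):
        return self.resid_sd if self.resid_sd is not None else self.sigma

    @property
    def resid(self):
        sd = self.resid_sd if self.resid_sd is not None else self.sigma
        # vector with exact ddof=1 standard deviation sd
        half = self.n_resid // 2
        base = np.concatenate([np.ones(half), -np.ones(half)])
        return base * sd * np.sqrt((len(base) - 1) / len(base))


@pytest.fixture
def stub_fit_factory():
    return StubFit
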