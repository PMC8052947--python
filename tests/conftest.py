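"""Shared fixtures: synthetic cohorts at the documented study conditions.

Cohort construction is expensive (tachogram simulation + full feature
extraction per patient), so the three cohorts used across the suite are
session-scoped:

* ``default_cohort`` — the documented default conditions (n=800, prevalence
  0.31, 12 informative clinical variables, MACE-shifted tachogram model).
* ``planted_cohort`` — two informative variables only, tachogram model
  identical between groups (for stepwise-recovery checks).
* ``null_cohort``    — no informative variables at all (for null-distribution
  checks).
"""

from __future__ import annotations

import numpy as np
import pytest

from hrnv.rr import DerivedRRSequence, RRSeries
from hrnv.synthetic import CohortSpec, RRModel, simulate_cohort

NULL_RR = RRModel(mace_shift_ms=0.0, hf_amp_mace_ms=18.0, noise_sd_mace_ms=24.0)

PLANTED_EFFECTS = {"troponin": 1.2, "diabetes": 1.1}


def make_seq(values, n: int = 1, m: int = 0, source_id: str = "test") -> DerivedRRSequence:
    return DerivedRRSequence(source_id=source_id, n=n, m=m,
                             values=np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def planted_cohort():
    spec = CohortSpec(n_patients=400, prevalence=0.31, seed=2,
                      effects=dict(PLANTED_EFFECTS), rr=NULL_RR)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    spec = CohortSpec(n_patients=250, prevalence=0.31, seed=3,
                      effects={}, rr=NULL_RR)
    return simulate_cohort(spec)
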