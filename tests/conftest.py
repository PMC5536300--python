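"""Shared fixtures.

The expensive end-to-end toy run (default synthetic cohort through
preprocessing, ICA at four model orders, both HPM stages, group stats,
Granger causality and classification) is session-scoped and shared by the
recovery, group-statistics and classification tests.
"""

import numpy as np
import pytest

from icahpm.cohort import default_spec, generate_cohort
from icahpm.pipeline import run_pipeline, validate_config

TOY_SEED = 7


@pytest.fixture(scope="session")
def toy_report():
    """Full pipeline report on the default toy cohort (20+20 subjects,
    K = 4 sources, desk-scale model orders 10..40)."""
    cfg = validate_config({"orders": "10:40:10", "seed": TOY_SEED})
    return run_pipeline(cfg, write_outputs=False)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 3+3-subject cohort for structural checks."""
    spec = default_spec(n_per_group=(3, 3), seed=5)
    series, truth = generate_cohort(spec)
    return spec, series, truth
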