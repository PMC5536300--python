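"""Small helpers shared across test modules."""

import numpy as np

from icahpm.cohort import SubjectSeries


def make_series(n_volumes=146, shape=(6, 6, 4), seed=0):
    rng = np.random.default_rng(seed)
    return SubjectSeries(
        subject_id="sub-001",
        group="control",
        age=25.0,
        sex="F",
        severity=None,
        data=rng.normal(size=shape + (n_volumes,)),
        mask=np.ones(shape, dtype=bool),
        tr_seconds=2.2,
        voxel_size_mm=(3.75, 3.75, 3.5),
        motion=np.zeros((n_volumes, 6)),
    )
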