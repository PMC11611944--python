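import numpy as np
import pytest

from tractadjust.data import SubjectTractTable


def make_table(lengths, metrics, subject_id="sub-000", metric_name="FA"):
    lengths = np.asarray(lengths, dtype=float)
    return SubjectTractTable(
        subject_id=subject_id,
        tract_ids=[f"t{i:03d}" for i in range(len(lengths))],
        lengths_mm=lengths,
        metrics=np.asarray(metrics, dtype=float),
        metric_name=metric_name,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blackman_table(rng):
    """82 tracts on a noisy linear-plateau curve (inflection 100 mm)."""
    lengths = rng.uniform(55, 160, 82)
    clean = 0.05 + 0.004 * np.minimum(lengths, 100.0)
    return make_table(lengths, clean + rng.normal(0, 0.02, 82))
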