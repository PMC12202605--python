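import numpy as np
import pytest

from dyngrnn import CohortManifest, ROITimeSeries, SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng):
    return ROITimeSeries(
        subject_id="s1",
        roi_labels=("A", "B", "C"),
        data=rng.standard_normal((3, 20)),
    )


def make_manifest(counts: dict[str, int]) -> CohortManifest:
    records = []
    k = 0
    for group, count in counts.items():
        for _ in range(count):
            records.append(SubjectRecord(subject_id=f"s{k:03d}", group=group))
            k += 1
    return CohortManifest(records=tuple(records), label_set=tuple(counts))


@pytest.fixture
def manifest_85():
    return make_manifest({"HC": 33, "EMCI": 29, "AD": 23})
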