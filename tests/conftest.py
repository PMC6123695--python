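import numpy as np
import pytest

from replimap.statmap import GroupMap, StatMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_statmap(data, mask=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    return StatMap(data=data, mask=np.asarray(mask, dtype=bool))


def make_groupmap(data, mask=None, k=4, label="P"):
    return GroupMap(
        zmap=make_statmap(data, mask), k=k, member_ids=tuple(range(k)), label=label
    )


@pytest.fixture
def small_signal_dataset():
    """A tiny signal-bearing synthetic dataset shared by several tests."""
    from replimap.synthetic import (
        Blob,
        SyntheticDatasetSpec,
        TruthSpec,
        generate_subject_maps,
    )

    truth = TruthSpec(
        grid_shape=(14, 14, 14),
        blobs=(Blob((7, 7, 7), 4.0, 1.0), Blob((3, 9, 5), 3.0, -0.8)),
    )
    spec = SyntheticDatasetSpec(
        truth=truth,
        n_subjects=12,
        n_runs=2,
        sigma_between=0.4,
        sigma_within=0.8,
        noise_fwhm=2.0,
        seed=7,
    )
    return generate_subject_maps(spec)
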