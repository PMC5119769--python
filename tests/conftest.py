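import numpy as np
import pytest

from dptsim.synthetic_dpt import DPTDataset, TaskLayout


@pytest.fixture
def abv_layout() -> TaskLayout:
    return TaskLayout.abv_style()


@pytest.fixture
def tlbs_layout() -> TaskLayout:
    return TaskLayout.tlbs_style()


@pytest.fixture
def make_dataset():
    """Build a dataset from (trial_type, rt[, subset_id]) tuples."""

    def _make(layout: TaskLayout, records) -> DPTDataset:
        return DPTDataset.from_trials(layout, records)

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160925)
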