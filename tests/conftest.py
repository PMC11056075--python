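import numpy as np
import pytest

from metapool.data import Design, MetaAnalysisDataset, Metric, Study


def make_dataset(ys, ses, designs=None, label="toy", metric=Metric.OR):
    designs = designs or [Design.RCT if i == 0 else Design.NRS for i in range(len(ys))]
    studies = [
        Study(f"s{i}", d, float(y), float(se))
        for i, (y, se, d) in enumerate(zip(ys, ses, designs))
    ]
    return MetaAnalysisDataset(label=label, metric=metric, studies=studies)


@pytest.fixture
def toy3():
    """Heterogeneous 3-study dataset used across oracle checks."""
    return make_dataset([0.0, 0.8, 1.6], [0.2, 0.2, 0.2])


@pytest.fixture
def mixed_design6():
    """3 RCT + 3 NRS with mild spread."""
    return make_dataset(
        [0.1, -0.2, 0.3, 0.0, 0.4, -0.1],
        [0.25, 0.3, 0.2, 0.35, 0.3, 0.25],
        designs=[Design.RCT] * 3 + [Design.NRS] * 3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
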