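import numpy as np
import pandas as pd
import pytest

from screenorm import ScreenStudy


def make_study(
    lib=(0.1, 0.3, 0.7),
    neg=(0.0, 0.02, -0.02),
    pos=(1.0, 1.05, 0.95),
    replicate="r1",
    cell_line="lineA",
    plate=None,
) -> pd.DataFrame:
    """One-replicate long-format block; concatenate blocks for multi-rep studies."""
    rows = []
    for i, v in enumerate(lib):
        rows.append((f"f{i:03d}", "lib", cell_line, replicate, plate, v))
    for i, v in enumerate(neg):
        rows.append((f"neg{i}", "neg", cell_line, replicate, plate, v))
    for i, v in enumerate(pos):
        rows.append((f"pos{i}", "pos", cell_line, replicate, plate, v))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "well_type", "cell_line", "replicate", "plate", "readout"],
    )


@pytest.fixture
def simple_study() -> ScreenStudy:
    return ScreenStudy(make_study())


@pytest.fixture
def two_replicate_scores() -> ScreenStudy:
    """Two replicates already on the score scale, second = 2 x first."""
    rng = np.random.default_rng(42)
    base = rng.normal(0.25, 0.2, size=200)
    a = make_study(lib=base, neg=(0.0, 0.01, -0.01), pos=(1.0, 0.99, 1.01),
                   replicate="r1")
    b = make_study(lib=2 * base, neg=(0.0, 0.02, -0.02), pos=(2.0, 1.98, 2.02),
                   replicate="r2", cell_line="lineB")
    return ScreenStudy(pd.concat([a, b], ignore_index=True))
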