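import numpy as np
import pytest

from crtmi.core_data import TrialDataset


def make_trial(
    arms,
    clusters,
    y1,
    y2,
    x=None,
    w=None,
    r1=None,
    r2=None,
):
    """Build a small TrialDataset from plain lists (NaN in y = missing)."""
    n = len(arms)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    return TrialDataset(
        individual_id=np.array([f"i{t}" for t in range(n)], dtype=object),
        cluster_id=np.asarray(clusters, dtype=object),
        arm=np.asarray(arms),
        x=np.zeros(n) if x is None else np.asarray(x, dtype=float),
        w=np.zeros(n) if w is None else np.asarray(w, dtype=float),
        y1=y1,
        y2=y2,
        r1=np.isnan(y1).astype(np.int8) if r1 is None else np.asarray(r1),
        r2=np.isnan(y2).astype(np.int8) if r2 is None else np.asarray(r2),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_complete():
    """Two arms, two clusters each, fully observed."""
    return make_trial(
        arms=[0, 0, 0, 0, 1, 1, 1, 1],
        clusters=["a", "a", "b", "b", "c", "c", "d", "d"],
        y1=[1.0, 1.0, 3.0, 3.0, 2.0, 2.0, 6.0, 6.0],
        y2=[0.5, 0.7, 1.5, 1.3, 1.0, 1.2, 3.0, 2.8],
    )
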