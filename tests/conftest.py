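import numpy as np
import pandas as pd
import pytest

from ethoscore import PoseTrack, default_geometry

COORDS = ("x", "y", "likelihood")


def make_track(frames, landmarks=("snout", "mid_body"), px_per_cm=1.0,
               fps=25.0, session_id="test"):
    """Build a PoseTrack from per-frame samples given in cm.

    ``frames`` is a list of dicts mapping landmark -> (x_cm, y_cm, lik);
    landmarks absent from a frame are missing-coded.
    """
    cols = {(lm, c): [] for lm in landmarks for c in COORDS}
    for sample in frames:
        for lm in landmarks:
            x, y, lik = sample.get(lm, (np.nan, np.nan, 0.0))
            cols[(lm, "x")].append(x * px_per_cm if np.isfinite(x) else np.nan)
            cols[(lm, "y")].append(y * px_per_cm if np.isfinite(y) else np.nan)
            cols[(lm, "likelihood")].append(lik)
    data = pd.DataFrame(cols, index=pd.RangeIndex(len(frames)))
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return PoseTrack(session_id=session_id, fps=fps, data=data)


@pytest.fixture
def geom():
    # px_per_cm=1 keeps cm/px identical for hand-built tracks
    return default_geometry(px_per_cm=1.0)


@pytest.fixture
def geom_px10():
    return default_geometry(px_per_cm=10.0)
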