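import numpy as np
import pandas as pd
import pytest

from filocausal import (
    CouplingParams,
    FilopodiumTrack,
    preprocess_track,
    simulate_dataset,
)


def make_track(track_id="t1", frame_interval=2.0, **columns) -> FilopodiumTrack:
    """Build a track from keyword column arrays; unspecified columns are NaN."""
    n = len(next(iter(columns.values())))
    data = {"frame": np.arange(1, n + 1)}
    for col in (
        "tip_fluor", "base_fluor", "body_fluor", "boundary_fluor",
        "length", "tip_movement", "base_movement", "waviness",
    ):
        data[col] = np.asarray(columns.get(col, np.full(n, np.nan)), dtype=float)
    if "frame" in columns:
        data["frame"] = np.asarray(columns["frame"])
    return FilopodiumTrack(track_id, frame_interval, pd.DataFrame(data))


@pytest.fixture(scope="session")
def coupled_dataset():
    """40 tracks, half strongly coupled at a 1-frame lag (dt = 2 s)."""
    params = CouplingParams(responder_fraction=0.5)
    tracks, truths = simulate_dataset(params, 40, seed=42)
    processed = [preprocess_track(t) for t in tracks]
    return tracks, truths, processed


@pytest.fixture(scope="session")
def decoupled_dataset():
    """30 tracks with movement independent of fluorescence."""
    params = CouplingParams(beta=0.0, responder_fraction=0.0)
    tracks, truths = simulate_dataset(params, 30, seed=7)
    processed = [preprocess_track(t) for t in tracks]
    return tracks, truths, processed
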