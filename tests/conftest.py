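"""Shared fixtures: small synthetic genomes and a lightly trained model.

Everything is generated programmatically and seeded; the expensive trained
model is session-scoped so interpretability and refinement tests share it.
"""

import numpy as np
import pytest
from hypothesis import settings

import encore

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from encore.simulate import SimConfig, simulate_dataset, simulate_tracks


@pytest.fixture(scope="session")
def small_sim():
    """Moderate-noise synthetic genome: dataset, truth and tracks."""
    cfg = SimConfig(n_positive=60, neg_ratio=10, noise_scale=0.3,
                    center_offset=400, seed=5)
    ds, truth = simulate_dataset(cfg)
    tracks, _ = simulate_tracks(cfg)
    return {"config": cfg, "dataset": ds, "truth": truth, "tracks": tracks}


@pytest.fixture(scope="session")
def trained_model(small_sim):
    """CNN trained briefly on the small synthetic dataset (separable)."""
    ds = small_sim["dataset"]
    est = encore.EnhancerClassifier(max_epochs=10, batch_size=16,
                                    random_state=5)
    est.fit(ds.X, ds.y)
    return est


@pytest.fixture()
def toy_tracks():
    """Five tiny constant-valued tracks on one 12 kb chromosome."""
    from encore.signal_io import AssayPanel, SignalTrack
    panel = AssayPanel()
    tracks = {}
    for i, assay in enumerate(panel.assays):
        tracks[assay] = SignalTrack(
            assay=assay,
            values={"chr1": np.full(12000, float(i + 1), dtype=np.float32)})
    return tracks
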