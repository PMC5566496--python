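import numpy as np
import pandas as pd
import pytest

from mucometa import nmr, synthetic as syn


@pytest.fixture(scope="session")
def cohort_meta():
    meta, _ = syn.simulate_metadata(syn.CohortConfig(seed=11))
    return meta


@pytest.fixture(scope="session")
def small_meta():
    meta, _ = syn.simulate_metadata(syn.CohortConfig(n_patients=4, seed=5))
    return meta


def spectra_frame_to_spectra(frame: pd.DataFrame, calibrated: bool = True):
    ppm = frame["ppm"].to_numpy()
    return [
        nmr.Spectrum(ppm=ppm, intensity=frame[c].to_numpy(), sample_id=c,
                     calibrated=calibrated)
        for c in frame.columns
        if c != "ppm"
    ]


@pytest.fixture()
def toy_matrix():
    """Small binned, excluded matrix (4 samples x 6 bins) for stage tests."""
    bins = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    X = np.abs(np.random.default_rng(3).normal(1.0, 0.2, size=(4, 6)))
    return nmr.SpectralMatrix(
        bins=bins, X=X, sample_ids=[f"s{i}" for i in range(4)],
        flags={"calibrated": True, "excluded": True, "normalized": False,
               "scaled": False},
    )
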