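import numpy as np
import pandas as pd
import pytest

import exomir


@pytest.fixture(scope="session")
def study_samples() -> pd.DataFrame:
    """Sample table of the 20-sample array cohort (C1-6, BD1-6, SZ1-8)
    with the published medication-class flags."""
    return exomir.datasets.load_study_metadata()


@pytest.fixture(scope="session")
def run_pipeline():
    """Factory: simulate a cohort and run it through flooring, filtering
    and normalization.  Returns (normalized matrix, metadata, truth)."""

    def _run(seed=0, **config_kwargs):
        cfg = exomir.SimConfig(seed=seed, **config_kwargs)
        expr, truth = exomir.simulate_expression(cfg)
        meta = exomir.simulate_metadata(cfg)
        floored, _ = exomir.floor_negatives(expr)
        norm = exomir.normalize_samples(exomir.filter_informative(floored))
        return norm, meta, truth

    return _run


@pytest.fixture(scope="session")
def fitted_sam(run_pipeline):
    """One SAM fit on a default spiked cohort, shared across tests."""
    norm, meta, truth = run_pipeline(seed=7)
    est = exomir.SamMulticlass(n_permutations=1000, random_state=7)
    est.fit(norm.to_numpy().T, meta["group"].to_numpy())
    return est, norm, meta, truth
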