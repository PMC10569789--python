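import numpy as np
import pytest

import cftrgate as cg


@pytest.fixture(scope="session")
def wt_scheme():
    return cg.make_preset("WT").scheme


@pytest.fixture(scope="session")
def wt_bursts(wt_scheme):
    """Burst table from a long exact simulation of the WT scheme.

    Shared across tests that compare Gillespie statistics against the
    closed-form summaries (the heavy part is simulated once per session).
    """
    traj = cg.simulate_trajectory(wt_scheme, n_bursts=100_000, seed=7, start="IB")
    b = traj.bursts()
    return b[b["terminated"] != "censored"]


@pytest.fixture(scope="session")
def corner_pipeline(tmp_path_factory):
    """Full-pipeline run over the four corner genotypes of the
    Q1371/G576 closure-rate mutant cycle (8 synthetic replicates each)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = cg.RunConfig(
        seed=11,
        genotypes=["hE1371Q", "hE1371Q_G576del", "hE1371S", "hE1371S_G576del"],
        output_dir=str(out),
        n_channels=1000,
        n_replicates=8,
        fs=50.0,
        f_acq=10.0,
        window=5.0,
    )
    return cg.run_pipeline(cfg), out
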