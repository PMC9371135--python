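import pandas as pd
import pytest

from aerofog.climate_sim import SimConfig
from aerofog.reporting import run_pipeline


@pytest.fixture(scope="session")
def day_run(tmp_path_factory):
    """One simulated day of the full pipeline, shared across tests."""
    out = tmp_path_factory.mktemp("run")
    path = run_pipeline(SimConfig(), days=1, seed=11, out_dir=out / "artifacts")
    return path


@pytest.fixture
def noiseless_config():
    return SimConfig(
        noise_sd={k: 0.0 for k in ("Ta", "RHa", "dtla", "RHc", "Lum", "T_sol", "T_res")}
    )
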