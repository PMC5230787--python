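import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kevtools import AnalysisConfig, SimulationConfig, reference_start_sites

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def reference_sites() -> pd.DataFrame:
    """Bundled 19-gene 5'-RACE reference set (one row per mapped 5' end)."""
    return reference_start_sites()


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    """A deterministic world: no noise, no dropout, no outliers."""
    return SimulationConfig(
        n_genes=200,
        frac_sensitive=0.05,
        frac_resistant=0.05,
        noise_cv=0.0,
        missing_prob=0.0,
        outlier_prob=0.0,
        seed=11,
    )
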