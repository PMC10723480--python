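import numpy as np
import pytest

from pscore import MetricSpec, NormativeTable, generate_metric_table

NEG_SKEW = MetricSpec("FA", "skew_normal", "negative", -6.0, (0.35, 0.65), (0.02, 0.05))
POS_SKEW = MetricSpec("MD", "skew_normal", "positive", 6.0, (6.5e-4, 9.0e-4), (2e-5, 6e-5))


@pytest.fixture(scope="session")
def dt_like_table() -> NormativeTable:
    """Tie-free negatively skewed 960 × 48 table (DT-metric sample size)."""
    return generate_metric_table(NEG_SKEW, 960, 48, seed=42)


@pytest.fixture(scope="session")
def map_like_table() -> NormativeTable:
    """Tie-free negatively skewed 912 × 48 table (MAP-metric sample size)."""
    spec = MetricSpec("PA", "skew_normal", "negative", -6.0, (0.55, 0.85), (0.02, 0.05))
    return generate_metric_table(spec, 912, 48, seed=42)


@pytest.fixture()
def small_table() -> NormativeTable:
    """Deterministic 10 × 3 table with distinct positive values."""
    rng = np.random.default_rng(7)
    return NormativeTable(rng.uniform(1.0, 2.0, size=(10, 3)),
                          participant_ids=[f"p{i}" for i in range(10)],
                          roi_labels=["gcc", "bcc", "scc"],
                          metric_name="FA")
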