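import numpy as np
import pytest

import bloomclock as bc


@pytest.fixture
def small_config():
    """Three well-separated planted modules, three trees, light noise."""
    return bc.SimulationConfig(
        n_genes=300,
        n_stage_modules=3,
        module_sizes=[40, 40, 40],
        peak_days=[-20, -8, 0],
        trees=[("T1", "A", 2019), ("T2", "B", 2019), ("T3", "C", 2019)],
        sampling_days=list(range(-32, 12, 2)),
        replicate_noise_sd=0.1,
        n_trend_genes=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_run():
    """Full default-condition dataset run through detection + staging."""
    cfg = bc.default_config(seed=42)
    matrix, meta, truth = bc.generate_timecourse(cfg)
    filtered, report = bc.variance_filter(matrix)
    partition = bc.detect_modules(filtered, power=6)
    bc.assign_stages(partition, meta)
    return {
        "config": cfg,
        "matrix": matrix,
        "metadata": meta,
        "truth": truth,
        "filtered": filtered,
        "filter_report": report,
        "partition": partition,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
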