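import numpy as np
import pytest

from stresslnc.config import PipelineConfig
from stresslnc.simulate import SimParams, simulate_study


def small_params(seed: int = 11) -> SimParams:
    """Down-scaled study conditions used across the suite: one 160 kb
    chromosome, 16 genes, 120 transcripts."""
    return SimParams(
        n_chrom=1,
        chrom_len=160_000,
        n_genes=16,
        n_transcripts=120,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """One simulated study directory shared by read-only tests."""
    d = tmp_path_factory.mktemp("study")
    truth, nat_truth, params = simulate_study(d, small_params())
    return {"dir": d, "truth": truth, "nat_truth": nat_truth, "params": params}


@pytest.fixture(scope="session")
def pipeline_result(small_study):
    """Full pipeline run on the shared study."""
    from stresslnc.pipeline import run_study

    return run_study(small_study["dir"], PipelineConfig(seed=11), n_structure=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
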