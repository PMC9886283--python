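import warnings

import numpy as np
import pytest

from gmpsig.pipeline import run_pipeline
from gmpsig.synthetic import SyntheticTruth, simulate_compendium
from gmpsig.types import GeneModulePair, PipelineConfig, TargetSpace

# pipeline settings matched to the synthetic scale (1,000-gene universe,
# 50-gene planted modules): extremes at the planted-module size and a
# gentle soft power keep the stages within their operating regime
SYNTH_CFG = dict(
    module_size=50, n_extreme=50, min_module_size=20, soft_power=2, rng_seed=7
)


@pytest.fixture(scope="session")
def default_truth():
    return SyntheticTruth(seed=7, outlier_frac=0.1)


@pytest.fixture(scope="session")
def compendium(default_truth):
    return simulate_compendium(default_truth)


@pytest.fixture(scope="session")
def pipeline_result(default_truth, compendium):
    M, anns = compendium
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(**SYNTH_CFG), M, anns)


@pytest.fixture(scope="session")
def space(pipeline_result):
    return pipeline_result.space


def random_space(
    n_targets: int,
    module_size: int = 50,
    universe_size: int = 1000,
    seed: int = 0,
    prefix: str = "T",
) -> TargetSpace:
    """Target space of uniformly random disjoint-up/down module pairs."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(universe_size)]
    arr = np.asarray(genes)
    gmps = {}
    for t in range(n_targets):
        pick = rng.choice(universe_size, size=2 * module_size, replace=False)
        tid = f"{prefix}{t + 1:03d}"
        gmps[tid] = GeneModulePair(
            target_id=tid,
            up=frozenset(arr[pick[:module_size]]),
            down=frozenset(arr[pick[module_size:]]),
        )
    return TargetSpace(gmps=gmps, universe=genes, module_size=module_size)
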