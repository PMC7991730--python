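import numpy as np
import pytest

import methrevert as mr
from methrevert.pipeline import StudyDesign


@pytest.fixture(scope="session")
def planted_study():
    """One full synthetic study at the design's group sizes (7/12/10) with
    20 reversible and 10 persistent genes planted among 200 (seed 1)."""
    cfg = mr.SimulationConfig(seed=1)
    callsets, promoters, truth = mr.simulate_methylome(cfg)
    groups = {s: label for label, ids in cfg.sample_ids().items() for s in ids}
    matrix = mr.build_matrix(callsets, groups)
    design = StudyDesign.from_groups(groups)
    return {
        "config": cfg,
        "callsets": callsets,
        "promoters": promoters,
        "truth": truth,
        "groups": groups,
        "matrix": matrix,
        "design": design,
    }


@pytest.fixture(scope="session")
def core_panel(planted_study):
    from methrevert.pipeline import run_core_panel

    return run_core_panel(
        planted_study["matrix"], planted_study["promoters"], planted_study["design"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
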