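import numpy as np
import pandas as pd
import pytest

import riskeq as rq
from riskeq.simulate import schemas_for


@pytest.fixture(scope="session")
def small_cohort():
    """One default synthetic cohort (245 patients) with ground truth."""
    cfg = rq.default_bsi_scenario(seed=11, n_patients=245)
    raw, truth = rq.generate(cfg)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def small_design(small_cohort):
    """The small cohort taken through the full encoding pipeline."""
    cfg, raw, truth = small_cohort
    clean, design, report = rq.encode_cohort(raw, schemas_for(cfg.variables), "BSI")
    design = rq.stratified_partition(design, test_fraction=0.2, k_folds=5, seed=11)
    return clean, design, report


def make_toy_design(n=400, p=12, informative=(0, 1), weights=(2.0, -1.5),
                    bias=-0.5, seed=0, k_folds=5):
    """Small planted-model design matrix for engine tests: p independent
    Bernoulli(0.4) condition columns, outcome from a logistic model over
    the informative ones."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, p)) < 0.4
    conds = [rq.Condition(f"v{j}", "eq", (True,)) for j in range(p)]
    r = bias + sum(w * X[:, j] for j, w in zip(informative, weights))
    y = (rng.random(n) < 1 / (1 + np.exp(-r))).astype(int)
    design = rq.BinaryDesign(
        X=pd.DataFrame(X.astype(int), columns=[c.name for c in conds]),
        conditions=conds,
        y=y,
    )
    truth = rq.RiskEquation(
        terms=[(conds[j], w) for j, w in zip(informative, weights)], bias=bias
    )
    return rq.stratified_partition(design, 0.2, k_folds, seed=seed), truth


@pytest.fixture(scope="session")
def toy_design():
    return make_toy_design()
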