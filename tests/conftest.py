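import logging

import numpy as np
import pandas as pd
import pytest

from longreg import ModelHyperparameters
from longreg.baselines import BaselineSpec, Method
from longreg.evaluation import CVConfig, cross_validate
from longreg.simdata import SimConfig, generate_problem

logging.getLogger("longreg").setLevel(logging.ERROR)


def make_problem(seed=0, **kw):
    return generate_problem(SimConfig(seed=seed, **kw))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cv_experiment():
    """Shared 20-replicate CV comparison on generator defaults.

    Heavy (several minutes); computed once and reused by the evaluation
    ordering tests and the acceptance criteria on qualitative orderings.
    Per replicate: mean CV correlation of the tuned full model, trace-only
    ablation, ridge and lasso on all visits, plus the full model restricted
    to the first visit only.
    """
    grid = tuple(float(x) for x in np.logspace(-2, 2, 5))
    full_grid = [ModelHyperparameters(gamma1=g1, gamma2=g2)
                 for g1, g2 in [(2, 0.2), (10, 1), (40, 4)]]
    trace_grid = [BaselineSpec(Method.TRACE_ONLY, penalty=p)
                  for p in (1.0, 4.0, 16.0, 64.0, 256.0)]
    methods = {
        "full": full_grid,
        "trace_only": trace_grid,
        "ridge": BaselineSpec(Method.RR, penalty_grid=grid),
        "lasso": BaselineSpec(Method.LASSO, penalty_grid=grid,
                              solver_max_iter=500),
    }
    rows = []
    for rep in range(20):
        prob = generate_problem(SimConfig(seed=900 + rep))
        report = cross_validate(prob.X, prob.Y, methods,
                                CVConfig(n_folds=5, seed=rep))
        bl_report = cross_validate(prob.X, prob.Y, {"full": full_grid},
                                   CVConfig(n_folds=5, seed=rep,
                                            time_subset=(0,)))
        rows.append({
            "replicate": rep,
            **{f"corr_{m}": v for m, v in report.mean_corr.items()},
            **{f"rmse_{m}": v for m, v in report.mean_rmse.items()},
            "corr_full_bl_only": bl_report.mean_corr["full"],
        })
    return pd.DataFrame(rows)
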