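import numpy as np
import pytest

import alscreen as als
from alscreen.pipeline import make_joint_fold_plan
from alscreen.targets import build_targets


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for unit tests (complete predictors)."""
    return als.generate_cohort(
        als.CohortConfig(
            n_individuals=200, n_predictors=40, n_informative=6,
            n_redundant_per_informative=1, effect_size=1.5,
            missing_rate=0.0, seed=7,
        )
    )


@pytest.fixture(scope="session")
def separable_cohort():
    """A strongly separable cohort: effect size 2, 10 informative + 40 noise."""
    return als.generate_cohort(
        als.CohortConfig(
            n_individuals=584, n_predictors=50, n_informative=10,
            n_redundant_per_informative=0, effect_size=2.0,
            missing_rate=0.0, seed=3,
        )
    )


@pytest.fixture(scope="session")
def separable_q_teachers(separable_cohort):
    """Two-stage teachers for all domains of the quantile definition,
    fitted once and shared across tests."""
    c = separable_cohort
    labs2 = build_targets(c, "Q", "M2")
    labs3 = build_targets(c, "Q", "M3")
    Y3 = np.column_stack([labs3[d].labels for d in c.domain_spec])
    plan = make_joint_fold_plan(Y3, k=5, seed=42)
    teachers = {
        d: als.fit_teacher(
            c.X_M2, c.X_M3,
            labs2[d].labels.to_numpy(), labs3[d].labels.to_numpy(), plan,
        )
        for d in c.domain_spec
    }
    return {"cohort": c, "labs2": labs2, "labs3": labs3, "Y3": Y3,
            "plan": plan, "teachers": teachers}
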