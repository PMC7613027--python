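"""Synthetic subject cohorts: the study conditions for recovery analyses.

Group-level generating distributions are diagonal Gaussians over transformed
parameters (logit alpha, log beta, logit w).  Means default to the flexible
model's fitted group parameters (alpha 0.56, beta 1.59, w 0.85 in the
dependent condition); SDs default to (1.0, 0.5, 1.5), the scale of
between-subject spread hierarchical fits estimate on cohorts of this design —
a 95% subject range of roughly alpha 0.15-0.90, beta 0.6-4.2, w 0.23-0.99.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hierfit import natural_params, transform_params
from .learner import ModelParams, run_model
from .task import TaskConfig, generate_trial_table

#: fitted group means used as generating means (flexible model)
GROUP_MEANS_FLEXIBLE = ModelParams(alpha=0.56, beta=1.59, w=0.85)
#: fitted group means for the fixed model
GROUP_MEANS_FIXED = ModelParams(alpha=0.65, beta=1.80, w=0.61)
#: generating group SDs over (logit alpha, log beta, logit w)
GROUP_SDS_TRANSFORMED = (1.0, 0.5, 1.5)


def sample_params(
    rng: np.random.Generator,
    n: int,
    means: ModelParams = GROUP_MEANS_FLEXIBLE,
    sds: Sequence[float] = GROUP_SDS_TRANSFORMED,
) -> List[ModelParams]:
    """Draw subject parameters from the transformed-space group Gaussian."""
    mean_t = transform_params(means)
    sds = np.asarray(sds, dtype=float)
    return [natural_params(mean_t + sds * rng.standard_normal(3)) for _ in range(n)]


def simulate_cohort(
    rng: np.random.Generator,
    n_subjects: int = 29,
    variant: str = "flexible",
    config: Optional[TaskConfig] = None,
    means: Optional[ModelParams] = None,
    sds: Sequence[float] = GROUP_SDS_TRANSFORMED,
) -> Tuple[List[pd.DataFrame], List[ModelParams]]:
    """Simulate a cohort of agents; returns (trial tables, true parameters)."""
    if config is None:
        config = TaskConfig.fmri()
    if means is None:
        means = GROUP_MEANS_FLEXIBLE if variant == "flexible" else GROUP_MEANS_FIXED
    params = sample_params(rng, n_subjects, means=means, sds=sds)
    tables = []
    for i, p in enumerate(params):
        trials = generate_trial_table(config, rng, subject=i)
        tables.append(run_model(trials, p, variant=variant, mode="simulate", rng=rng))
    return tables, params
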