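"""Shared fixtures: the default synthetic cohort and expensive pipeline runs.

Session-scoped so the 33-participant cohort, its day-feature table and the
full leave-one-subject-out run are computed once and reused across tests.
"""

import numpy as np
import pytest

from actiphen.pipeline import PipelineConfig, build_day_features, run_outcome
from actiphen.synthetic_cohort import CohortConfig, generate_cohort

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def day_features(default_cohort):
    return build_day_features(default_cohort.series, default_cohort.sleep_logs)


@pytest.fixture(scope="session")
def dx_run(default_cohort, day_features):
    """Full-default LOSO run for the clinician-diagnosis outcome."""
    return run_outcome(day_features, default_cohort.outcomes, "dx", seed=COHORT_SEED)


@pytest.fixture(scope="session")
def labels_by_pid(default_cohort):
    return {o.participant_id: int(o.ptsd_dx) for o in default_cohort.outcomes}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


SWEEP_SEEDS = range(1, 21)
EFFECT_FEATURES = ["restfulness", "waso", "efficiency", "fragmentation",
                   "acrophase_time"]


def _person_means(seed, config_kwargs):
    cohort = generate_cohort(CohortConfig(seed=seed, **config_kwargs))
    rows = build_day_features(cohort.series, cohort.sleep_logs)
    per = rows.groupby("participant_id").mean(numeric_only=True)
    dx = per.index.map(
        {o.participant_id: o.ptsd_dx for o in cohort.outcomes}
    ).to_numpy(dtype=int)
    return cohort, per, dx


@pytest.fixture(scope="session")
def multi_seed_sweep():
    """Default-config cohorts over 20 seeds: group differences, rating
    correlation, control acrophase, PCL-flag prevalences."""
    out = {"diffs": [], "qr_corr": [], "control_acrophase": [],
           "n_pcl31": [], "n_pcl38": []}
    for seed in SWEEP_SEEDS:
        cohort, per, dx = _person_means(seed, {})
        out["diffs"].append({
            f: per[f][dx == 1].mean() - per[f][dx == 0].mean()
            for f in EFFECT_FEATURES
        })
        out["qr_corr"].append(
            float(np.corrcoef(per["quality"], per["restfulness"])[0, 1])
        )
        out["control_acrophase"].append(float(per["acrophase_time"][dx == 0].mean()))
        out["n_pcl31"].append(sum(o.pcl31 for o in cohort.outcomes))
        out["n_pcl38"].append(sum(o.pcl38 for o in cohort.outcomes))
    return out


@pytest.fixture(scope="session")
def null_sweep():
    """Zero-effect cohorts over 20 seeds: mean group difference and mean
    pooled SE per feature."""
    from actiphen.epoch_io import FEATURE_NAMES

    zero = dict(delta_restfulness=0.0, delta_waso_minutes=0.0,
                delta_efficiency=0.0, delta_fragmentation=0.0,
                delta_acrophase_hours=0.0)
    diffs = {f: [] for f in FEATURE_NAMES}
    ses = {f: [] for f in FEATURE_NAMES}
    for seed in SWEEP_SEEDS:
        _, per, dx = _person_means(seed, zero)
        n1, n0 = int(dx.sum()), int((1 - dx).sum())
        for f in FEATURE_NAMES:
            a, b = per[f][dx == 1], per[f][dx == 0]
            diffs[f].append(a.mean() - b.mean())
            sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n0 - 1) * b.var(ddof=1))
                         / (n1 + n0 - 2))
            ses[f].append(sp * np.sqrt(1 / n1 + 1 / n0))
    return {
        "diff_se": {
            f: (float(np.mean(diffs[f])), float(np.mean(ses[f])))
            for f in FEATURE_NAMES
        }
    }
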