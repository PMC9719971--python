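import numpy as np
import pytest

from abxcease.preprocess import (
    FeatureNormalizer,
    SplitSpec,
    StayTimeline,
    build_timelines,
    compute_treatment_course,
    filter_cohort,
    split_by_stay,
)
from abxcease.simulate import SimConfig, simulate_cohort


def make_timeline(stay_id, abx_flags, n_features=3, los=5.0, mortality=0, seed=0, features=None):
    """Hand-rolled StayTimeline for unit tests."""
    rng = np.random.default_rng(seed + stay_id)
    flags = np.asarray(abx_flags, dtype=int)
    t = flags.size
    if features is None:
        features = rng.normal(size=(t, n_features))
    features = np.asarray(features, dtype=float)
    cum, course = compute_treatment_course(flags)
    return StayTimeline(
        stay_id=stay_id,
        features=features,
        missing_mask=np.zeros_like(features, dtype=np.uint8),
        feature_names=[f"f{i:02d}" for i in range(features.shape[1])],
        abx_status=flags,
        cum_treatment_len=cum,
        course=course,
        age_at_admission=60.0,
        los_label=float(los),
        mortality_label=int(mortality),
        normalised=True,
    )


def prepare_cohort(config: SimConfig, split_seed=None):
    """simulate -> timelines -> filter -> split -> normalise; returns
    (cohort, processed timelines, split dict)."""
    cohort = simulate_cohort(config)
    raw = build_timelines(cohort.events, cohort.abx, cohort.labels)
    kept, _ = filter_cohort(raw)
    spec = SplitSpec(seed=config.seed if split_seed is None else split_seed)
    split = split_by_stay([tl.stay_id for tl in kept], spec)
    train_ids = set(split["train"])
    norm = FeatureNormalizer().fit([tl for tl in kept if tl.stay_id in train_ids])
    return cohort, norm.transform(kept), split


@pytest.fixture(scope="session")
def small_cohort():
    """120-stay cohort shared by cheap integration tests."""
    return prepare_cohort(SimConfig(n_stays=120, seed=9))
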