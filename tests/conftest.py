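import numpy as np
import pytest

from weanwave.signals import middle_window
from weanwave.synthetic import CohortSpec, gen_cohort
from weanwave.variability import FeatureConfig, extract_features, features_to_frame

#: Short-trial settings used by unit tests: a 120 s "trial" with a 60 s
#: analysis window keeps every extractor exercised (3750 waveform samples
#: cover the default DFA bands) while staying fast.
SHORT_TRIAL = dict(sbt_duration=120.0)
SHORT_WINDOW = 60.0


@pytest.fixture(scope="session")
def small_cohort():
    """A small but two-group synthetic cohort of full SBT records."""
    records, manifest = gen_cohort(
        CohortSpec(n_success=8, n_failure=6, seed=42, **SHORT_TRIAL)
    )
    return records, manifest


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature table extracted from the small cohort (60 s window)."""
    records, _ = small_cohort
    fc = FeatureConfig(window_s=SHORT_WINDOW)
    vectors = [
        extract_features(middle_window(r, SHORT_WINDOW), fc) for r in records
    ]
    return features_to_frame(vectors)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
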