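import numpy as np
import pytest

from gamnn import Dataset, FeatureSchema, FeatureSpec


@pytest.fixture
def mixed_schema() -> FeatureSchema:
    """Three continuous + two binary features, perioperative-style names."""
    return FeatureSchema(
        specs=(
            FeatureSpec("AGE", "continuous"),
            FeatureSpec("ASA_SCORE", "continuous", impute_policy="constant", constant_value=3),
            FeatureSpec("MIN_DBP", "continuous", clip_min=5.0, clip_max=150.0),
            FeatureSpec("ART_LINE_YN", "binary"),
            FeatureSpec("HCUP_CAT_1_YN", "binary"),
        ),
        outcome_name="IN_HOSPITAL_MORTALITY",
    )


@pytest.fixture
def small_dataset(mixed_schema) -> Dataset:
    rng = np.random.default_rng(7)
    n = 40
    values = np.column_stack(
        [
            rng.normal(55, 15, n),
            rng.integers(1, 5, n).astype(float),
            rng.normal(60, 12, n),
            (rng.random(n) < 0.2).astype(float),
            (rng.random(n) < 0.1).astype(float),
        ]
    )
    labels = (rng.random(n) < 0.3).astype(int)
    return Dataset(values, labels, mixed_schema.feature_names)


def random_model_params(model, rng: np.random.Generator, scale: float = 0.8) -> None:
    """Randomize every parameter of a GamnnModel in place (for property tests
    over arbitrary weight settings, not just trained ones)."""
    for k, v in model.params.items():
        model.params[k] = rng.normal(0.0, scale, size=np.shape(v))
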