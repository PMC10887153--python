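import numpy as np
import pytest

from trialfc import (BrainMask, FCMap, HemodynamicModel, PipelineConfig,
                     StimulusParadigm, SyntheticSpec, TrialWindow,
                     default_paradigm, make_subject_run)
from trialfc.hrf import default_paradigm as _default_paradigm


@pytest.fixture(scope="session")
def model() -> HemodynamicModel:
    return HemodynamicModel()


@pytest.fixture(scope="session")
def paradigm() -> StimulusParadigm:
    return default_paradigm()


@pytest.fixture(scope="session")
def single_trial_paradigm() -> StimulusParadigm:
    return StimulusParadigm(
        trial_onsets=(0.0,), trial_labels=("FT",),
        task_duration=6.0, rest_duration=24.0, run_length=30.0, tr=2.5,
    )


def small_spec(**overrides) -> SyntheticSpec:
    """Desk-scale synthetic spec for fast unit tests."""
    defaults = dict(grid_shape=(14, 14, 10), seed=0)
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_subject():
    """One small-grid synthetic subject shared across tests."""
    return make_subject_run(small_spec(seed=7))


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(seed=7, simulate={"grid_shape": (14, 14, 10)})


def toy_map(values: np.ndarray, mask: BrainMask | None = None,
            label: str = "WR", trial: int = 1,
            subject: str = "S01") -> FCMap:
    """Wrap a flat or 3D array of r values as an FCMap on a full mask."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(-1, 1, 1)
    if mask is None:
        mask = BrainMask(np.ones(values.shape, dtype=bool))
    window = TrialWindow(subject_id=subject, task_label=label,
                         trial_index=trial, start_volume=0, n_volumes=12)
    out = np.full(values.shape, np.nan)
    out[mask.inside] = values[mask.inside]
    return FCMap(values=out, mask=mask, window=window, n_samples=12)
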