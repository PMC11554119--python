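import numpy as np
import pytest

from pescale.design import build_tpm, generate_run
from pescale.features import correlation_rdm, trial_surprise
from pescale.stimuli import default_stimulus_set
from pescale.synth import synth_feature_hierarchy


@pytest.fixture(scope="session")
def stimuli():
    return default_stimulus_set()


@pytest.fixture(scope="session")
def tpm(stimuli):
    return build_tpm(stimuli)


@pytest.fixture(scope="session")
def run_events(tpm):
    return generate_run(tpm, rng_seed=7)


@pytest.fixture(scope="session")
def feature_layers(stimuli):
    return synth_feature_hierarchy(stimulus_ids=stimuli.stimulus_ids, rng_seed=11)


@pytest.fixture(scope="session")
def layer_rdms(feature_layers):
    return {fs.layer_id: correlation_rdm(fs) for fs in feature_layers}


@pytest.fixture(scope="session")
def surprise_layer8(layer_rdms, run_events, stimuli):
    return trial_surprise(layer_rdms["layer8"], run_events, stimuli,
                          model_id="layer8")


def spaced_events(n_trials: int = 12, spacing: float = 20.0, stimuli=None):
    """Widely spaced go trials cycling through the 8 images (for LSS/LSA)."""
    import pandas as pd
    if stimuli is None:
        stimuli = default_stimulus_set()
    rows = []
    onset = 10.0
    for k in range(n_trials):
        img = stimuli.stimulus_ids[k % 8]
        cue = stimuli.cue_letters[(k + 1) % 8]     # unexpected pairing
        cond = "expected" if stimuli.stimulus_for_cue(cue) == img else "unexpected"
        rows.append({"onset": onset, "duration": 0.5, "trial_type": cond,
                     "cue": cue, "stim_id": img, "condition": cond,
                     "iti": spacing})
        onset += spacing
    return pd.DataFrame(rows)
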