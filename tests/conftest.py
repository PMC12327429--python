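import numpy as np
import pytest

from prpkit.features import make_inventory
from prpkit.prp import PRPSet


@pytest.fixture(scope="session")
def inventory8():
    return make_inventory(8, 0.5, seed=3)


def _separable_prp_sets(n_participants=8, n_phonemes=6, n_electrodes=8,
                        n_times=32, fs=64.0, noise=0.05, seed=0):
    """PRP sets whose per-phoneme templates are far apart relative to noise."""
    from scipy.ndimage import gaussian_filter1d
    rng = np.random.default_rng(seed)
    labels = [f"P{k}" for k in range(n_phonemes)]
    # smooth, low-frequency templates: the classifier's pooling stages keep
    # this band, so separability is limited only by the (small) noise
    templates = {lab: 3.0 * gaussian_filter1d(
        rng.normal(size=(n_electrodes, n_times)), 2.5, axis=-1)
        for lab in labels}
    sets = []
    for i in range(n_participants):
        prps = {lab: templates[lab] + noise * rng.normal(
            size=(n_electrodes, n_times)) for lab in labels}
        sets.append(PRPSet(participant_id=f"sub{i:02d}", group="G", fs=fs,
                           window=(0.0, 0.5), prps=prps,
                           counts={lab: 50 for lab in labels}))
    return sets


@pytest.fixture(scope="session")
def separable_prp_sets():
    return _separable_prp_sets()


@pytest.fixture(scope="session")
def trained_separable_cv(separable_prp_sets):
    """A cross-validated classifier on cleanly separable PRPs, with models."""
    from prpkit.decoder import ClassifierSpec, train_eval_cv
    spec = ClassifierSpec(folds=4, max_epochs=40, patience=12, lr=2e-3)
    return train_eval_cv(separable_prp_sets, spec, seed=7, return_models=True)
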