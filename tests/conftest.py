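import numpy as np
import pytest

from smfdx import preprocess, synth


@pytest.fixture(scope="session")
def small_cohort():
    """A small jittered cohort with three planted markers, plus its truth."""
    cfg = synth.CohortConfig(
        n_per_group=10, n_features=50, n_differential=3,
        mz_range=(100.0, 400.0), mz_jitter_ppm=50.0, dropout_prob=0.1, seed=11,
    )
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    spectra, truth = small_cohort
    return preprocess.preprocess_cohort(spectra, truth.manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def truth_matrix(seed, n_per_group=40, n_features=100, n_differential=3,
                 **kwargs):
    """Raw-intensity FeatureMatrix straight from the generator's ground truth.

    Rendering dense profile spectra is the slow part of cohort generation;
    matrix-level tests only need the realized apex intensities, so the grid
    is coarsened to keep these cohorts cheap.
    """
    kwargs.setdefault("mz_range", (100.0, 1000.0))
    lo, hi = kwargs["mz_range"]
    kwargs.setdefault("grid_step", (hi - lo) / 200.0)
    cfg = synth.CohortConfig(
        n_per_group=n_per_group, n_features=n_features,
        n_differential=n_differential, seed=seed, **kwargs,
    )
    _, truth = synth.generate_cohort(cfg)
    return truth.to_feature_matrix(), truth
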