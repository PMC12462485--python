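import numpy as np
import pytest

from beliefdyn import ratings, synth


@pytest.fixture(scope="session")
def small_cfg():
    """A fast movie-like cohort for module-level tests."""
    return synth.movie_config(n_subjects=12, n_voxels_per_roi=16, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return synth.make_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_updates(small_cfg, small_dataset):
    """Smoothed courses and binarized update points for the small cohort."""
    courses, ups = {}, {}
    for d in synth.DOMAINS:
        course = ratings.smooth_course(
            ratings.rasterize_events(small_dataset.rater_logs[d],
                                     small_cfg.tr, small_cfg.n_trs))
        courses[d] = course
        ups[d] = ratings.binarize_updates(course, 2.0)
    return courses, ups


def brute_force_loo_isc(data):
    """Two-pass leave-one-out ISC oracle (explicit loops)."""
    n_sub, _ = data.shape
    out = np.empty(n_sub)
    for s in range(n_sub):
        others = np.mean([data[j] for j in range(n_sub) if j != s], axis=0)
        out[s] = np.corrcoef(data[s], others)[0, 1]
    return out
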