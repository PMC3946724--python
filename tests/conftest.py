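import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_calibrated(groups):
    """Build (outcomes, probabilities) calibrated in-sample by construction.

    ``groups`` is a list of (n_diseased, n_total) pairs; each group gets
    probability n_diseased / n_total, so for every distinct predicted value
    the mean outcome among subjects holding it equals that value.
    """
    outcomes, probs = [], []
    for n_dis, n_tot in groups:
        assert 0 <= n_dis <= n_tot and n_tot >= 1
        p = n_dis / n_tot
        outcomes += [1.0] * n_dis + [0.0] * (n_tot - n_dis)
        probs += [p] * n_tot
    return np.asarray(outcomes), np.asarray(probs)


def random_calibrated_groups(rng, n_groups=None, max_group=9):
    """Random group spec for make_calibrated with both classes present."""
    while True:
        k = n_groups or rng.integers(2, 7)
        groups = []
        for _ in range(k):
            n_tot = int(rng.integers(1, max_group + 1))
            groups.append((int(rng.integers(0, n_tot + 1)), n_tot))
        d, p = make_calibrated(groups)
        if 0 < d.sum() < d.size:
            return groups


@pytest.fixture
def rng():
    return np.random.default_rng(20240307)


def random_labeled(rng, n=None, tie_grid=None):
    """Random outcomes/probabilities with both classes, optional tie grid."""
    n = n or int(rng.integers(4, 60))
    while True:
        d = rng.integers(0, 2, n).astype(float)
        if 0 < d.sum() < n:
            break
    if tie_grid:
        p = rng.integers(0, tie_grid, n) / (tie_grid - 1)
    else:
        p = rng.random(n)
    return d, p
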