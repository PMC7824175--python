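import numpy as np
import pytest

import topoga as tg


@pytest.fixture(scope="session")
def small_instance():
    """Desk-size synthetic half-embryo shared by read-only tests."""
    cfg = tg.SyntheticConfig(
        n_bins=60, n_cells=80, n_informative_genes=12, n_noise_genes=6,
        dropout_rate=0.1, flip_rate=0.01, seed=11,
    )
    return cfg, *tg.make_instance(cfg)


@pytest.fixture(scope="session")
def small_evaluator(small_instance):
    _, atlas, geom, expr, _ = small_instance
    return tg.build_evaluator(atlas, geom, expr)


def random_score_matrix(rng, n_cells, n_bins):
    return tg.ScoreMatrix(values=rng.uniform(-1, 1, size=(n_cells, n_bins)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
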