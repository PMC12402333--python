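import numpy as np
import pandas as pd
import pytest

from libio.matrix import ExpressionMatrix
from libio.simulate import SimConfig, simulate_mouse_timecourse

# A scaled-down mouse time course shared by tests that only need the
# data structure, not full statistical power.
SMALL_SIM = dict(
    n_responders=3,
    n_nonresponders=3,
    n_genes=60,
    n_marker_genes_per_type=5,
    n_cells_per_sample=80,
    n_clones_per_subject=40,
)


@pytest.fixture(scope="session")
def small_mouse():
    cfg = SimConfig(seed=11, **SMALL_SIM)
    counts, ann, clonotypes, manifest, truth = simulate_mouse_timecourse(cfg)
    return {
        "cfg": cfg,
        "counts": counts,
        "ann": ann,
        "clonotypes": clonotypes,
        "manifest": manifest,
        "truth": truth,
    }


@pytest.fixture
def tiny_counts():
    """3 genes x 4 cells of raw counts."""
    values = pd.DataFrame(
        [[4.0, 0.0, 1.0, 2.0], [0.0, 0.0, 3.0, 2.0], [0.0, 1.0, 0.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return ExpressionMatrix(values, "counts")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
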