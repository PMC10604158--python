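import numpy as np
import pytest

from isletdx import SynthSpec, generate, preprocess
from isletdx.data import (LabelVector, LABEL_DIABETIC, LABEL_NON_DIABETIC)


@pytest.fixture(scope="session")
def desk_dataset():
    """Desk-scale two-class dataset with four planted windows."""
    x, y, truth = generate(SynthSpec(seed=11))
    return x, y, truth


@pytest.fixture(scope="session")
def desk_preprocessed(desk_dataset):
    x, y, truth = desk_dataset
    return preprocess(x, n_top_genes=x.n_genes), y, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def two_class_labels(n_dia: int, n_ctrl: int) -> LabelVector:
    ids = [f"D{i}" for i in range(n_dia)] + [f"N{i}" for i in range(n_ctrl)]
    return LabelVector(ids, [LABEL_DIABETIC] * n_dia
                       + [LABEL_NON_DIABETIC] * n_ctrl)


@pytest.fixture()
def blob_task(rng):
    """Well-separated (6 sigma) two-Gaussian task, 20/50 training split."""
    xtr = np.vstack([rng.normal(0, 1, (20, 2)) + 6.0,
                     rng.normal(0, 1, (50, 2))])
    ytr = two_class_labels(20, 50)
    xte = np.vstack([rng.normal(0, 1, (10, 2)) + 6.0,
                     rng.normal(0, 1, (10, 2))])
    yte = np.asarray([LABEL_DIABETIC] * 10 + [LABEL_NON_DIABETIC] * 10,
                     dtype=object)
    return xtr, ytr, xte, yte
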