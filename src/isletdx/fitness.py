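"""Class-separability fitness shared by the swarm selectors.

All three metaheuristics score a candidate gene/feature subset by the mean
per-feature Fisher discriminant ratio

    FDR_g = (mu_g,dia - mu_g,ctrl)^2 / (s2_g,dia + s2_g,ctrl + eps),

a filter fitness that keeps selection classifier-independent and cheap: the
per-feature ratios are precomputed once, so one candidate evaluation is a
top-k decode plus a mean.
"""

from __future__ import annotations

import numpy as np

from .data import LabelVector, LABEL_DIABETIC

EPS = 1e-12


def fisher_ratios(values: np.ndarray, y: LabelVector) -> np.ndarray:
    """Per-row Fisher discriminant ratio of a features x samples matrix."""
    mask = y.binary(LABEL_DIABETIC).astype(bool)
    if mask.all() or not mask.any():
        raise ValueError("both classes must be present")
    a, b = values[:, mask], values[:, ~mask]
    gap = a.mean(axis=1) - b.mean(axis=1)
    s2 = a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)
    return gap ** 2 / (s2 + EPS)


def decode_top_k(position: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest position weights, ties to the lowest index."""
    # argsort on (-value, index) via stable sort on negated values
    order = np.argsort(-position, kind="stable")[:k]
    return np.sort(order)


def subset_fitness(position: np.ndarray, ratios: np.ndarray, k: int) -> float:
    """Mean Fisher ratio over the decoded top-k subset."""
    idx = np.argpartition(-position, k - 1)[:k]
    return float(ratios[idx].mean())
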