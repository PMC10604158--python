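"""Descriptive statistics of reduced class blocks and plot-data exports.

A class block is the features x samples sub-matrix of one class.  The four
moments are pooled over every entry of the block; kurtosis is Fisher excess
and skewness is the adjusted Fisher-Pearson form.  The within-class
correlation scalar is the mean of pairwise Pearson r over sample pairs, and
the between-class association is the first canonical correlation with
features as observations and samples as variables (the only orientation in
which the two class blocks share an axis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class StatsSummary:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    pcc: float
    cca: float


def descriptive(values) -> tuple[float, float, float, float]:
    """Pooled (mean, variance, skewness, excess kurtosis) of a block.

    Variance uses divisor n.  A constant block has variance 0 and
    undefined (NaN) skewness/kurtosis.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise ValueError("need at least 3 values")
    mean = float(v.mean())
    var = float(v.var())
    if var == 0.0:
        log.warning("constant input: skewness/kurtosis undefined")
        return mean, 0.0, float("nan"), float("nan")
    skew = float(sps.skew(v, bias=False))
    kurt = float(sps.kurtosis(v, fisher=True, bias=False))
    return mean, var, skew, kurt


def pearson_cc(values) -> float:
    """Mean pairwise Pearson correlation over sample columns of one class
    block.  Zero-variance columns are skipped (with a warning)."""
    v = np.asarray(values, dtype=float)
    if v.shape[1] < 2:
        raise ValueError("need >= 2 samples in the class")
    keep = np.flatnonzero(v.std(axis=0) > 0)
    if keep.size < v.shape[1]:
        log.warning("pearson_cc: skipping %d zero-variance column(s)",
                    v.shape[1] - keep.size)
    if keep.size < 2:
        raise ValueError("fewer than 2 usable columns")
    r = np.corrcoef(v[:, keep].T)
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


def cca_first(a, b, reg: float = 1e-8) -> float:
    """First canonical correlation between two blocks sharing the row axis.

    Rows are observations and columns variables; computed from the
    whitened cross-covariance's largest singular value, with ``reg`` ridge
    regularization on both covariances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("blocks must share the observation (row) axis")
    n = a.shape[0]
    if n <= max(a.shape[1], b.shape[1]):
        raise ValueError("fewer observations than variables; sub-sample the "
                         "variable axis or transpose the blocks")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    saa = ac.T @ ac / n + reg * np.eye(a.shape[1])
    sbb = bc.T @ bc / n + reg * np.eye(b.shape[1])
    sab = ac.T @ bc / n

    def inv_sqrt(m):
        w, u = np.linalg.eigh(m)
        w = np.clip(w, reg, None)
        return u @ np.diag(w ** -0.5) @ u.T

    m = inv_sqrt(saa) @ sab @ inv_sqrt(sbb)
    s = np.linalg.svd(m, compute_uv=False)
    return float(min(s[0], 1.0))


def class_summary(values_dia, values_ctrl) -> tuple[StatsSummary, StatsSummary]:
    """The printed-table statistics for the two class blocks of one DR
    method (one row set per class; CCA is shared)."""
    cca = cca_first(values_dia, values_ctrl)
    out = []
    for block in (values_dia, values_ctrl):
        mean, var, skew, kurt = descriptive(block)
        out.append(StatsSummary(mean, var, skew, kurt, pearson_cc(block), cca))
    return out[0], out[1]


def plot_data(values, kind: str, bins: int = 20,
              sample_pair: tuple[int, int] = (0, 1)):
    """Plot-ready tables: per-sample histograms, normal-probability pairs,
    or a two-sample scatter.  No rendering happens here."""
    import pandas as pd
    v = np.asarray(values, dtype=float)
    if kind == "histogram":
        rows = []
        for j in range(v.shape[1]):
            counts, edges = np.histogram(v[:, j], bins=bins)
            for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
                rows.append({"sample": j, "bin_lo": lo, "bin_hi": hi,
                             "count": int(c)})
        return pd.DataFrame(rows)
    if kind == "normal_probability":
        rows = []
        for j in range(v.shape[1]):
            ordered = np.sort(v[:, j])
            qs = sps.norm.ppf((np.arange(1, ordered.size + 1) - 0.5)
                              / ordered.size)
            for q, val in zip(qs, ordered):
                rows.append({"sample": j, "quantile": q, "value": val})
        return pd.DataFrame(rows)
    if kind == "scatter":
        i, j = sample_pair
        return pd.DataFrame({"x": v[:, i], "y": v[:, j]})
    raise ValueError(f"unknown plot kind {kind!r}")


def variance_ratio_pvalue(a, b) -> float:
    """Two-sided variance-ratio (F) test p-value between two flat samples."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    f = a.var(ddof=1) / b.var(ddof=1)
    d1, d2 = a.size - 1, b.size - 1
    p = sps.f.sf(f, d1, d2)
    return float(2 * min(p, 1 - p))
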