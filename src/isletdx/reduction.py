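"""Windowed dimensionality reduction of the gene axis.

All three deterministic operators split the gene axis into consecutive,
non-overlapping windows of a fixed length (default 8, reproducing the
22,960 -> 2,870 reduction of the full-scale pipeline) and summarize each
window per sample:

* ``bessel_dr`` projects the window onto J_0 sampled at equispaced
  abscissae on (0, x_max] (x_max defaulting to the first zero of J_0 so the
  basis vector has no sign change), normalized by the basis norm;
* ``dct_dr`` keeps the leading coefficient(s) of the orthonormal type-II
  DCT of the window;
* ``lslr_dr`` projects the window onto its leading least-squares direction
  (first principal axis of the gene-centered window block), the rank-1
  summary minimizing reconstruction SSE.

They are deterministic, label-free and (bessel/dct) linear in the input.
A window that does not divide the gene count is zero-padded at the end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct as _dct

from .bessel import BesselBasis, j0_first_zero
from .data import ExpressionMatrix

log = logging.getLogger(__name__)

_J0_FIRST_ZERO = 2.404825557695773  # refined at import-check time in tests


@dataclass
class ReducedMatrix:
    """Features x samples matrix produced by one DR (or selection) method."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match identifiers")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values,
                            index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=self.sample_ids)


def _check_input(x: ExpressionMatrix, window: int) -> None:
    if isinstance(x, ReducedMatrix):
        raise TypeError(f"matrix already reduced with method {x.method!r}; "
                        "operators cannot be applied twice")
    if not isinstance(x, ExpressionMatrix):
        raise TypeError("expected an ExpressionMatrix")
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > x.n_genes:
        raise ValueError("window exceeds gene count")


def _windows(values: np.ndarray, window: int) -> np.ndarray:
    """(n_windows, window, n_samples) view with a zero-padded last window."""
    g, s = values.shape
    n_win = math.ceil(g / window)
    padded = np.zeros((n_win * window, s))
    padded[:g] = values
    return padded.reshape(n_win, window, s)


def make_bessel_basis(window: int, order_max: int = 5,
                      x_max: float | None = None) -> BesselBasis:
    """Basis sampled at ``window`` equispaced abscissae on (0, x_max]."""
    if x_max is None:
        x_max = _J0_FIRST_ZERO
    abscissae = np.linspace(x_max / window, x_max, window)
    return BesselBasis.build(order_max, abscissae)


def bessel_dr(x: ExpressionMatrix, window: int = 8,
              basis: BesselBasis | None = None) -> ReducedMatrix:
    """One J_0-projection coefficient per window per sample."""
    _check_input(x, window)
    if basis is None:
        basis = make_bessel_basis(window)
    b = basis.j0_vector()
    if b.shape[0] != window:
        raise ValueError(f"basis has {b.shape[0]} abscissae, window is {window}")
    blocks = _windows(x.values, window)
    feats = np.einsum("wks,k->ws", blocks, b) / np.linalg.norm(b)
    ids = [f"w{i:04d}" for i in range(blocks.shape[0])]
    return ReducedMatrix(ids, list(x.sample_ids), feats, "bessel")


def dct_dr(x: ExpressionMatrix, window: int = 8, n_coeffs: int = 1) -> ReducedMatrix:
    """First ``n_coeffs`` orthonormal DCT-II coefficients per window."""
    _check_input(x, window)
    if not 1 <= n_coeffs <= window:
        raise ValueError("need 1 <= n_coeffs <= window")
    blocks = _windows(x.values, window)
    coeffs = _dct(blocks, type=2, norm="ortho", axis=1)[:, :n_coeffs, :]
    n_win = blocks.shape[0]
    if n_coeffs == 1:
        feats = coeffs[:, 0, :]
        ids = [f"w{i:04d}" for i in range(n_win)]
    else:
        feats = coeffs.reshape(n_win * n_coeffs, -1)
        ids = [f"w{i:04d}c{c}" for i in range(n_win) for c in range(n_coeffs)]
    return ReducedMatrix(ids, list(x.sample_ids), feats, "dct")


def dct_window(v: np.ndarray) -> np.ndarray:
    """Full orthonormal DCT-II of one window (test/diagnostic helper)."""
    return _dct(np.asarray(v, dtype=float), type=2, norm="ortho")


def lslr_dr(x: ExpressionMatrix, labels_unused=None, window: int = 8) -> ReducedMatrix:
    """Leading least-squares direction per window; label-free.

    The direction is estimated from the gene-centered window block; each
    sample's feature is the projection of its raw window vector onto that
    direction, with the sign fixed so the largest-magnitude loading is
    positive.  An all-constant window yields a zero direction and feature 0
    (with a logged warning).
    """
    _check_input(x, window)
    if x.n_samples < 2:
        raise ValueError("need >= 2 samples")
    blocks = _windows(x.values, window)
    n_win = blocks.shape[0]
    feats = np.zeros((n_win, x.n_samples))
    degenerate = 0
    for i in range(n_win):
        block = blocks[i]                      # window x samples
        centered = block - block.mean(axis=1, keepdims=True)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        if s[0] <= 1e-12 * max(1.0, np.abs(block).max()):
            degenerate += 1
            continue
        direction = u[:, 0]
        if direction[np.argmax(np.abs(direction))] < 0:
            direction = -direction
        feats[i] = direction @ block
    if degenerate:
        log.warning("lslr_dr: %d all-constant window(s) mapped to feature 0",
                    degenerate)
    ids = [f"w{i:04d}" for i in range(n_win)]
    return ReducedMatrix(ids, list(x.sample_ids), feats, "lslr")


def lslr_window_sse(block: np.ndarray) -> float:
    """Rank-1 reconstruction SSE of one gene-centered window block."""
    centered = block - block.mean(axis=1, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    return float((s[1:] ** 2).sum())
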