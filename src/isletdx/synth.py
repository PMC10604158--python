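"""Two-class synthetic expression matrices with planted window structure.

The generator emulates the shape of a human pancreatic-islet microarray
study: log10-scale intensities, a 20-vs-50 class imbalance and a
configurable set of "informative" gene windows whose class means differ by
a stated effect size (in units of the noise SD, on the log scale).  Signal
is added on the log scale *before* the per-sample standardization performed
by :func:`isletdx.data.preprocess`, which attenuates but does not erase
between-class shifts because standardization is per sample, not per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, LabelVector, ValidationError, \
    LABEL_DIABETIC, LABEL_NON_DIABETIC


@dataclass
class SynthSpec:
    """Conditions for one synthetic dataset.

    ``effect_size`` is the class-mean difference on the log10 scale in units
    of ``noise_sd``; ``base_intensity`` is the raw-scale typical intensity
    (log10 of it is the mean log intensity).  ``gene_spread_sd`` gives genes
    distinct baselines so the peak-intensity filter has something to rank.
    """

    n_genes: int = 2296
    n_dia: int = 20
    n_ctrl: int = 50
    window: int = 8
    n_informative_windows: int = 4
    effect_size: float = 2.0
    noise_sd: float = 0.3
    base_intensity: float = 300.0
    gene_spread_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_dia, self.n_ctrl, self.window) <= 0:
            raise ValidationError("n_genes, n_dia, n_ctrl and window must be positive")
        if self.n_informative_windows < 0:
            raise ValidationError("n_informative_windows must be >= 0")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0 or self.base_intensity <= 0:
            raise ValidationError("noise_sd and base_intensity must be > 0")
        if self.n_informative_windows * self.window > self.n_genes:
            raise ValidationError("informative windows do not fit in the gene axis")


@dataclass
class GroundTruth:
    """Which genes / windows carry planted signal."""

    informative_gene_indices: set[int] = field(default_factory=set)
    informative_window_indices: set[int] = field(default_factory=set)

    def recall(self, selected: "set[int] | list[int]") -> float:
        """Fraction of planted genes present in ``selected`` indices."""
        if not self.informative_gene_indices:
            return float("nan")
        hit = len(self.informative_gene_indices & set(selected))
        return hit / len(self.informative_gene_indices)


def generate(spec: SynthSpec) -> tuple[ExpressionMatrix, LabelVector, GroundTruth]:
    """Draw one dataset; fully reproducible from ``spec.seed``.

    Raw intensities are ``10 ** (base + gene offset + signal + noise)`` so
    that ``preprocess`` reproduces the log/standardize regime exactly.
    Diabetic samples get ``+ effect_size * noise_sd`` on the log scale in
    every gene of every informative window; all other genes are identically
    distributed across classes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_dia + spec.n_ctrl
    base = np.log10(spec.base_intensity)
    gene_base = base + rng.normal(0.0, spec.gene_spread_sd, size=spec.n_genes)

    n_windows = spec.n_genes // spec.window
    if spec.n_informative_windows > n_windows:
        raise ValidationError("more informative windows than whole windows")
    winners = rng.choice(n_windows, size=spec.n_informative_windows, replace=False)
    gene_idx: set[int] = set()
    for w in winners:
        gene_idx.update(range(w * spec.window, (w + 1) * spec.window))

    log_vals = gene_base[:, None] + rng.normal(0.0, spec.noise_sd,
                                               size=(spec.n_genes, n))
    # diabetic columns first, then controls
    if gene_idx:
        rows = sorted(gene_idx)
        log_vals[np.ix_(rows, range(spec.n_dia))] += spec.effect_size * spec.noise_sd

    labels = [LABEL_DIABETIC] * spec.n_dia + [LABEL_NON_DIABETIC] * spec.n_ctrl
    sample_ids = [f"D{i + 1:03d}" for i in range(spec.n_dia)] + \
                 [f"N{i + 1:03d}" for i in range(spec.n_ctrl)]
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    x = ExpressionMatrix(gene_ids, sample_ids, 10.0 ** log_vals)
    y = LabelVector(list(sample_ids), labels)
    truth = GroundTruth(gene_idx, set(int(w) for w in winners))
    return x, y, truth
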