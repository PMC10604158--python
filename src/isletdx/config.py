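"""Every tunable of the pipeline in one validated record.

Defaults reproduce the full-scale study shape (22,960 genes kept, window 8
-> 2,870 windowed features, keep fraction 0.1 -> 287 selected) and the
printed classifier hyperparameters; the synthetic desk scale is a 10x
linear shrink of that pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class PipelineConfig:
    # preprocessing
    n_top_genes: int = 22_960
    log_base: float = 10.0
    # dimensionality reduction
    dr_window: int = 8
    dct_n_coeffs: int = 1
    # feature selection
    fs_keep_fraction: float = 0.1
    # swarm sizes / iterations
    swarm_size: int = 20
    swarm_iterations: int = 100
    # target encoding
    t_nd: float = 0.1
    t_dia: float = 0.85
    decision_threshold: float | None = None  # None -> midpoint
    lor_threshold: float = 0.5               # printed alternative: 0.48
    # classifier hyperparameters (printed defaults)
    svm_linear_c: float = 0.85
    svm_poly_c: float = 0.76
    svm_poly_gamma: "float | str" = 10.0
    svm_poly_degree: int = 2
    svm_rbf_c: float = 1.0
    svm_rbf_gamma: "float | str" = 100.0   # "scale" = 1/(F * Var), data-driven
    sdc_lambda: float = 0.5
    lr_learning_rate: float = 0.01
    gmm_components: int = 2
    bldc_alpha: float = 1.0
    bldc_beta: float = 10.0
    # cross-validation
    cv_folds: int = 10
    stratified: bool = True
    # master seed; per-stage seeds are derived from it
    seed: int = 0

    def validate(self) -> None:
        if self.n_top_genes <= 0:
            raise ValueError("n_top_genes must be positive")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")
        if self.dr_window < 2:
            raise ValueError("dr_window must be >= 2")
        if not 0 < self.fs_keep_fraction <= 1:
            raise ValueError("fs_keep_fraction must be in (0, 1]")
        if abs(self.t_dia - self.t_nd) < 0.5:
            raise ValueError(
                f"|t_dia - t_nd| = {abs(self.t_dia - self.t_nd):.3f} < 0.5; "
                "class targets must differ by at least 0.5")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
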