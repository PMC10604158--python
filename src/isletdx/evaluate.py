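"""Cross-validation, confusion matrices, the six-metric suite, the
confusion-matrix consistency solver and the DR x FS x classifier grid.

The positive class is diabetic throughout.  Fold metrics are aggregated by
pooling the per-fold confusion matrices, which yields integer counts on the
full sample set and therefore metrics expressible exactly at n = 70.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold

from .algae import AAAParams, aaa_reduce
from .classifiers import (CLASSIFIER_NAMES, TargetEncoding, make_classifier,
                          BaseClassifier)
from .config import PipelineConfig
from .data import ExpressionMatrix, LabelVector, LABEL_DIABETIC, preprocess
from .reduction import ReducedMatrix, bessel_dr, dct_dr, lslr_dr
from .selection import DOAParams, EHOParams, eho_select, doa_select

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)


@dataclass
class MetricSet:
    accuracy: float
    f1: float
    mcc: float
    error_rate: float
    fm: float
    kappa: float
    po: float
    pe: float
    degenerate: bool = False


def confusion(y_true: LabelVector, y_pred) -> ConfusionMatrix:
    """Counts with diabetic as the positive class."""
    pred = np.asarray(y_pred, dtype=object)
    true = y_true.as_array()
    if pred.shape != true.shape:
        raise ValueError("length mismatch between truth and predictions")
    pos = true == LABEL_DIABETIC
    hit = pred == LABEL_DIABETIC
    return ConfusionMatrix(int((pos & hit).sum()), int((pos & ~hit).sum()),
                           int((~pos & hit).sum()), int((~pos & ~hit).sum()))


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, F1, MCC, error rate, Fowlkes-Mallows and Cohen's kappa.

    Any metric with a zero denominator is reported as 0 and the result is
    flagged degenerate (this matches the printed MCC = kappa = 0 row of a
    chance-level classifier with an empty margin)."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    degenerate = False
    acc = (tp + tn) / n
    err = (fp + fn) / n
    f1_den = 2 * tp + fp + fn
    f1 = 2 * tp / f1_den if f1_den else 0.0
    if f1_den == 0:
        degenerate = True
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)
    else:
        mcc, degenerate = 0.0, True
    if tp + fp and tp + fn:
        fm = math.sqrt(tp / (tp + fp) * tp / (tp + fn))
    else:
        fm, degenerate = 0.0, True
    po = acc
    pe = ((tp + fp) * (tp + fn) + (fp + tn) * (fn + tn)) / n ** 2
    if pe != 1.0:
        kappa = (po - pe) / (1.0 - pe)
    else:
        kappa, degenerate = 0.0, True
    return MetricSet(acc, f1, mcc, err, fm, kappa, po, pe, degenerate)


def solve_confusion(n_pos: int, n_neg: int, accuracy: float, f1: float,
                    tol: float = 5e-5) -> ConfusionMatrix:
    """The unique integer confusion matrix on (n_pos, n_neg) samples whose
    accuracy and F1 match the given (possibly truncated) values.

    Exhaustive search over all (fn, fp) pairs; raises if no matrix is
    consistent or if several are (listing the candidates)."""
    if not (0 <= accuracy <= 1 and 0 <= f1 <= 1):
        raise ValueError("accuracy and f1 must be in [0, 1]")
    n = n_pos + n_neg
    found: list[ConfusionMatrix] = []
    for fn in range(n_pos + 1):
        tp = n_pos - fn
        for fp in range(n_neg + 1):
            tn = n_neg - fp
            acc = (tp + tn) / n
            den = 2 * tp + fp + fn
            f1v = 2 * tp / den if den else 0.0
            if abs(acc - accuracy) <= tol and abs(f1v - f1) <= tol:
                found.append(ConfusionMatrix(tp, fn, fp, tn))
    if not found:
        raise ValueError(f"inconsistent row: no confusion matrix on "
                         f"({n_pos}, {n_neg}) matches accuracy={accuracy}, f1={f1}")
    if len(found) > 1:
        raise ValueError(f"ambiguous row: candidates {found}")
    return found[0]


def mse(observed, target) -> float:
    """Mean squared error between observed and target vectors."""
    o = np.asarray(observed, dtype=float)
    t = np.asarray(target, dtype=float)
    if o.shape != t.shape:
        raise ValueError("length mismatch")
    if o.size == 0:
        raise ValueError("empty input")
    return float(np.mean((o - t) ** 2))


@dataclass
class CVPlan:
    k: int
    fold_of: np.ndarray          # sample index -> fold index
    stratified: bool
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test


def make_folds(y: LabelVector, k: int = 10, stratified: bool = True,
               seed: int = 0) -> CVPlan:
    """Deterministic (per seed) k-fold partition, stratified by default so
    every fold keeps the 20:50 class proportions."""
    n = len(y)
    if k > n:
        raise ValueError("k exceeds the sample count")
    if stratified:
        counts = y.class_counts()
        if k > min(v for v in counts.values() if v > 0):
            raise ValueError("k exceeds the smallest class count")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y.binary())
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    fold_of = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(splits):
        fold_of[test] = f
    return CVPlan(k, fold_of, stratified, seed)


DR_METHODS = ("bessel", "dct", "lslr", "aaa")
FS_METHODS = ("none", "eho", "doa")


def _classifier_overrides(name: str, cfg: PipelineConfig) -> dict:
    return {
        "lr": {"learning_rate": cfg.lr_learning_rate},
        "gmm": {"g": cfg.gmm_components},
        "bldc": {"alpha": cfg.bldc_alpha, "beta": cfg.bldc_beta},
        "lor": {"threshold": cfg.lor_threshold},
        "sdc": {"lam": cfg.sdc_lambda},
        "svm_l": {"C": cfg.svm_linear_c},
        "svm_poly": {"C": cfg.svm_poly_c, "gamma": cfg.svm_poly_gamma,
                     "degree": cfg.svm_poly_degree},
        "svm_rbf": {"C": cfg.svm_rbf_c, "gamma": cfg.svm_rbf_gamma},
    }.get(name, {})


def evaluate_classifier(model: BaseClassifier, values: np.ndarray,
                        y: LabelVector, plan: CVPlan,
                        encoding: TargetEncoding) -> dict:
    """Pooled-confusion cross-validation of one fitted-from-scratch-per-fold
    classifier on a features x samples matrix."""
    pooled = ConfusionMatrix(0, 0, 0, 0)
    tr_mse, te_mse = [], []
    for f in range(plan.k):
        tr, te = plan.train_test(f)
        xtr, xte = values[:, tr].T, values[:, te].T
        ytr, yte = y.subset(tr), y.subset(te)
        model.fit(xtr, ytr)
        pred = model.predict(xte)
        pooled = pooled + confusion(yte, pred)
        tr_mse.append(mse(model.continuous(xtr), encoding.encode(ytr)))
        te_mse.append(mse(model.continuous(xte), encoding.encode(yte)))
    m = metrics(pooled)
    return {"cm": pooled, "metrics": m,
            "train_mse": float(np.mean(tr_mse)),
            "test_mse": float(np.mean(te_mse))}


def run_grid(x: ExpressionMatrix, y: LabelVector,
             cfg: PipelineConfig | None = None,
             dr_methods=DR_METHODS, fs_methods=FS_METHODS,
             classifiers=CLASSIFIER_NAMES,
             preprocessed: bool = False) -> pd.DataFrame:
    """Full DR x FS x classifier sweep (4 x 3 x 10 = 120 rows by default).

    Deterministic, label-free DR (bessel/dct/lslr) runs once on the full
    matrix; label-dependent stages (AAA gene selection, EHO/DOA feature
    selection) are re-fit inside every training fold so no test label leaks
    into selection.  A stage failure marks the row failed and the grid
    continues.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    xp = x if preprocessed else preprocess(x, cfg.n_top_genes, cfg.log_base)
    enc = TargetEncoding(cfg.t_nd, cfg.t_dia, cfg.decision_threshold)
    plan = make_folds(y, cfg.cv_folds, cfg.stratified, cfg.seed)

    def stage_seed(*tags: str) -> int:
        h = zlib.crc32("/".join(tags).encode())
        return int(np.random.SeedSequence([cfg.seed, h]).generate_state(1)[0]
                   % (2 ** 31))

    d_out = math.ceil(xp.n_genes / cfg.dr_window)
    reduced: dict[str, np.ndarray] = {}
    fold_reduced: dict[str, list[np.ndarray]] = {}
    for dr in dr_methods:
        if dr == "bessel":
            reduced[dr] = bessel_dr(xp, cfg.dr_window).values
        elif dr == "dct":
            reduced[dr] = dct_dr(xp, cfg.dr_window, cfg.dct_n_coeffs).values
        elif dr == "lslr":
            reduced[dr] = lslr_dr(xp, window=cfg.dr_window).values
        elif dr == "aaa":
            mats = []
            for f in range(plan.k):
                tr, _ = plan.train_test(f)
                sub = ExpressionMatrix(list(xp.gene_ids),
                                       [xp.sample_ids[i] for i in tr],
                                       xp.values[:, tr])
                params = AAAParams(n_colonies=cfg.swarm_size,
                                   iterations=cfg.swarm_iterations,
                                   seed=stage_seed("aaa", str(f)))
                _, idx = aaa_reduce(sub, y.subset(tr), d_out, params)
                mats.append(xp.values[idx])          # selection applied to all samples
            fold_reduced[dr] = mats
        else:
            raise ValueError(f"unknown DR method {dr!r}")

    k_fs = max(1, math.ceil(d_out * cfg.fs_keep_fraction))
    rows = []
    for dr in dr_methods:
        per_fold = fold_reduced.get(dr)
        for fs in fs_methods:
            # per-fold feature masks, shared by the ten classifiers
            masks: list[np.ndarray | None] = []
            try:
                for f in range(plan.k):
                    vals = per_fold[f] if per_fold is not None else reduced[dr]
                    if fs == "none":
                        masks.append(None)
                        continue
                    tr, _ = plan.train_test(f)
                    block = ReducedMatrix([f"f{i}" for i in range(vals.shape[0])],
                                          [y.sample_ids[i] for i in tr],
                                          vals[:, tr], dr)
                    seed = stage_seed(dr, fs, str(f))
                    if fs == "eho":
                        mask = eho_select(block, y.subset(tr), k_fs,
                                          EHOParams(n_elephants=cfg.swarm_size,
                                                    iterations=cfg.swarm_iterations,
                                                    seed=seed))
                    elif fs == "doa":
                        mask = doa_select(block, y.subset(tr), k_fs,
                                          DOAParams(n_flies=cfg.swarm_size,
                                                    iterations=cfg.swarm_iterations,
                                                    seed=seed))
                    else:
                        raise ValueError(f"unknown FS method {fs!r}")
                    masks.append(np.asarray(mask.selected))
            except Exception as exc:          # noqa: BLE001 - row-level isolation
                log.warning("selection failed for %s/%s: %s", dr, fs, exc)
                for clf in classifiers:
                    rows.append({"dr": dr, "fs": fs, "classifier": clf,
                                 "failed": True, "error": str(exc)})
                continue
            for clf in classifiers:
                try:
                    overrides = _classifier_overrides(clf, cfg)
                    if clf in ("gmm", "em"):
                        overrides = {**overrides,
                                     "seed": stage_seed(dr, fs, clf)}
                    pooled = ConfusionMatrix(0, 0, 0, 0)
                    tr_mse, te_mse = [], []
                    for f in range(plan.k):
                        vals = per_fold[f] if per_fold is not None else reduced[dr]
                        if masks[f] is not None:
                            vals = vals[masks[f]]
                        tr, te = plan.train_test(f)
                        model = make_classifier(clf, encoding=enc, **overrides)
                        model.fit(vals[:, tr].T, y.subset(tr))
                        pooled = pooled + confusion(y.subset(te),
                                                    model.predict(vals[:, te].T))
                        tr_mse.append(mse(model.continuous(vals[:, tr].T),
                                          enc.encode(y.subset(tr))))
                        te_mse.append(mse(model.continuous(vals[:, te].T),
                                          enc.encode(y.subset(te))))
                    m = metrics(pooled)
                    rows.append({"dr": dr, "fs": fs, "classifier": clf,
                                 "failed": False, "error": "",
                                 "tp": pooled.tp, "fn": pooled.fn,
                                 "fp": pooled.fp, "tn": pooled.tn,
                                 "accuracy": m.accuracy, "f1": m.f1,
                                 "mcc": m.mcc, "error_rate": m.error_rate,
                                 "fm": m.fm, "kappa": m.kappa,
                                 "train_mse": float(np.mean(tr_mse)),
                                 "test_mse": float(np.mean(te_mse))})
                except Exception as exc:      # noqa: BLE001 - row-level isolation
                    log.warning("grid row %s/%s/%s failed: %s", dr, fs, clf, exc)
                    rows.append({"dr": dr, "fs": fs, "classifier": clf,
                                 "failed": True, "error": str(exc)})
    return pd.DataFrame(rows)
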