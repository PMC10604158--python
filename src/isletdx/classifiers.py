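"""Ten two-class classifiers behind a common fit/predict contract.

Regression-style models (NLR, LR, BLDC) are trained against numeric class
targets: non-diabetic -> t_nd (default 0.1) and diabetic -> t_dia (default
0.85), a valid encoding only when the targets differ by at least 0.5;
decisions threshold the continuous output at the midpoint.  Likelihood and
margin models (GMM, EM, LoR, SDC, SVM) use their native decision rules.
Every iterative fitter records a loss trace.

Sample orientation is samples x features throughout this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .data import LabelVector, LABEL_DIABETIC, LABEL_NON_DIABETIC

log = logging.getLogger(__name__)

# class order used for index-based tie-breaks: diabetic is class 0
CLASS_ORDER = (LABEL_DIABETIC, LABEL_NON_DIABETIC)


@dataclass
class TargetEncoding:
    """Numeric targets for the two classes plus a decision threshold."""

    t_nd: float = 0.1
    t_dia: float = 0.85
    decision_threshold: float | None = None

    def __post_init__(self) -> None:
        if abs(self.t_dia - self.t_nd) < 0.5:
            raise ValueError(
                f"|t_dia - t_nd| = {abs(self.t_dia - self.t_nd):.3f} < 0.5; "
                "targets must differ by at least 0.5")
        if self.decision_threshold is None:
            self.decision_threshold = 0.5 * (self.t_nd + self.t_dia)
        if not min(self.t_nd, self.t_dia) < self.decision_threshold < max(self.t_nd, self.t_dia):
            raise ValueError("decision threshold must lie between the targets")

    def encode(self, y: LabelVector) -> np.ndarray:
        return np.where(y.binary(LABEL_DIABETIC) == 1, self.t_dia, self.t_nd)

    def decide(self, scores: np.ndarray) -> np.ndarray:
        """Labels from continuous outputs; a score exactly at the threshold
        is non-diabetic (documented tie rule)."""
        return np.where(scores > self.decision_threshold,
                        LABEL_DIABETIC, LABEL_NON_DIABETIC)


def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _check_two_classes(y: LabelVector) -> None:
    counts = y.class_counts()
    if min(counts.values()) == 0:
        raise ValueError("training requires both classes present")


class BaseClassifier:
    """fit(X, y) / predict(X) / continuous(X) contract."""

    kind: str = "base"

    def __init__(self, encoding: TargetEncoding | None = None):
        self.encoding = encoding or TargetEncoding()
        self.training_log: list[float] = []

    def fit(self, x, y: LabelVector):
        raise NotImplementedError

    def predict(self, x) -> np.ndarray:
        raise NotImplementedError

    def continuous(self, x) -> np.ndarray:
        """Continuous output in target space, used for the MSE audit.

        Decision-only models report the encoded value of their predicted
        label."""
        lab = self.predict(x)
        return np.where(lab == LABEL_DIABETIC, self.encoding.t_dia,
                        self.encoding.t_nd)


# ------------------------------------------------------------------ NLR

def _sigmoid(z):
    return expit(z)


class NLRClassifier(BaseClassifier):
    """Single-sigmoid nonlinear regression t0 + t1 * sigmoid(t2 + x.w),
    fit by Levenberg-Marquardt on the squared-error objective.

    Accepted LM steps never increase the objective; the damping multiplier
    grows on rejection and shrinks on acceptance.
    """

    kind = "nlr"

    def __init__(self, max_iter: int = 100, tol: float = 1e-10,
                 tau0: float = 1e-3, encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        self.max_iter = max_iter
        self.tol = tol
        self.tau0 = tau0
        self.theta_: np.ndarray | None = None

    @staticmethod
    def _predict_theta(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        t0, t1, t2 = theta[:3]
        w = theta[3:]
        return t0 + t1 * _sigmoid(t2 + x @ w)

    @staticmethod
    def _jacobian(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        t1 = theta[1]
        s = _sigmoid(theta[2] + x @ theta[3:])
        ds = s * (1.0 - s)
        n = x.shape[0]
        jac = np.empty((n, 3 + x.shape[1]))
        jac[:, 0] = 1.0
        jac[:, 1] = s
        jac[:, 2] = t1 * ds
        jac[:, 3:] = (t1 * ds)[:, None] * x
        return jac

    def fit(self, x, y: LabelVector | np.ndarray):
        x = _as_matrix(x)
        targets = self.encoding.encode(y) if isinstance(y, LabelVector) \
            else np.asarray(y, dtype=float)
        theta = np.zeros(3 + x.shape[1])
        theta[1] = 1.0
        tau = self.tau0
        resid = targets - self._predict_theta(theta, x)
        sse = float(resid @ resid)
        self.training_log = [sse]
        for _ in range(self.max_iter):
            jac = self._jacobian(theta, x)
            g = jac.T @ resid
            h = jac.T @ jac
            stepped = False
            for _try in range(50):
                try:
                    delta = np.linalg.solve(h + tau * np.eye(h.shape[0]), g)
                except np.linalg.LinAlgError:
                    tau *= 10.0
                    continue
                cand = theta + delta
                r2 = targets - self._predict_theta(cand, x)
                s2 = float(r2 @ r2)
                if s2 <= sse:
                    theta, resid = cand, r2
                    improvement = sse - s2
                    sse = s2
                    tau = max(tau / 10.0, 1e-12)
                    stepped = True
                    break
                tau *= 10.0
            if not stepped:
                raise RuntimeError(
                    f"LM diverged: damping exhausted, trace={self.training_log[-5:]}")
            self.training_log.append(sse)
            if improvement < self.tol * (1.0 + sse):
                break
        self.theta_ = theta
        return self

    def continuous(self, x) -> np.ndarray:
        return self._predict_theta(self.theta_, _as_matrix(x))

    def predict(self, x) -> np.ndarray:
        return self.encoding.decide(self.continuous(x))


def lm_damped_step(jac: np.ndarray, resid: np.ndarray, tau: float) -> np.ndarray:
    """One damped normal-equations step (J'J + tau I) d = J'r, exposed for
    the heavy-damping limit check."""
    h = jac.T @ jac
    return np.linalg.solve(h + tau * np.eye(h.shape[0]), jac.T @ resid)


# ------------------------------------------------------------------- LR

class LRClassifier(BaseClassifier):
    """Linear regression onto the class targets by batch gradient descent
    with cost R(theta) = 1/(2m) sum (g_theta(x_i) - y_i)^2.

    Features are standardized internally (gradient descent at a fixed rate
    assumes comparably scaled inputs); the scaling is undone at predict
    time, so the model is equivalent to one fit on raw features."""

    kind = "lr"

    def __init__(self, learning_rate: float = 0.01, iters: int = 2000,
                 standardize: bool = True,
                 encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        self.learning_rate = learning_rate
        self.iters = iters
        self.standardize = standardize
        self.theta_: np.ndarray | None = None
        self.center_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.center_ is None:
            return x
        return (x - self.center_) / self.scale_

    def fit(self, x, y: LabelVector | np.ndarray):
        x = _as_matrix(x)
        targets = self.encoding.encode(y) if isinstance(y, LabelVector) \
            else np.asarray(y, dtype=float)
        if self.standardize:
            self.center_ = x.mean(axis=0)
            sd = x.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.center_ = self.scale_ = None
        x = self._transform(x)
        m = x.shape[0]
        xb = np.hstack([np.ones((m, 1)), x])
        theta = np.zeros(xb.shape[1])
        self.training_log = []
        for _ in range(self.iters):
            err = xb @ theta - targets
            cost = float(err @ err) / (2 * m)
            self.training_log.append(cost)
            if cost > 1e6:
                raise RuntimeError(
                    "gradient descent diverged; try a smaller learning rate")
            theta -= self.learning_rate / m * (xb.T @ err)
        self.theta_ = theta
        return self

    def continuous(self, x) -> np.ndarray:
        x = self._transform(_as_matrix(x))
        return np.hstack([np.ones((x.shape[0], 1)), x]) @ self.theta_

    def predict(self, x) -> np.ndarray:
        return self.encoding.decide(self.continuous(x))


# ----------------------------------------------------------- mixtures (EM)

def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    diff = x - mean
    maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def fit_mixture(x: np.ndarray, g: int, rng: np.random.Generator,
                max_iter: int = 200, tol: float = 1e-8, reg: float = 1e-6):
    """EM fit of a g-component full-covariance Gaussian mixture.

    Returns (weights, means, covs, loglik_trace, responsibilities); the
    log-likelihood trace is non-decreasing (EM guarantee).  An emptied
    component is re-seeded from a random data point.
    """
    n, d = x.shape
    if n <= g:
        raise ValueError("need more samples than components")
    idx = rng.choice(n, size=g, replace=False)
    means = x[idx].copy()
    base_cov = np.cov(x.T).reshape(d, d) + reg * np.eye(d)
    # nearest-seed hard assignment for the starting responsibilities keeps
    # separated clusters from collapsing onto a shared broad component
    d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    resp = np.zeros((n, g))
    resp[np.arange(n), np.argmin(d2, axis=1)] = 1.0
    covs = np.empty((g, d, d))
    for j in range(g):
        nk = resp[:, j].sum()
        if nk >= 2:
            diff = x - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk \
                + reg * np.eye(d)
        else:
            covs[j] = base_cov.copy()
    weights = resp.mean(axis=0) + 1e-12
    weights /= weights.sum()
    trace: list[float] = []
    for _ in range(max_iter):
        logp = np.stack([np.log(weights[j]) + _log_gauss(x, means[j], covs[j])
                         for j in range(g)], axis=1)
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        nk = resp.sum(axis=0)
        for j in range(g):
            if nk[j] < 1e-8:          # empty component: re-seed
                log.warning("mixture component %d emptied; re-seeding", j)
                means[j] = x[rng.integers(n)]
                covs[j] = base_cov.copy()
                nk[j] = 1.0
                resp[:, j] = 1.0 / n
        weights = nk / nk.sum()
        for j in range(g):
            means[j] = resp[:, j] @ x / nk[j]
            diff = x - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j] \
                + reg * np.eye(d)
        if trace and ll - trace[-1] < tol * (1.0 + abs(ll)):
            trace.append(ll)
            break
        trace.append(ll)
    return weights, means, covs, trace, resp


class GMMClassifier(BaseClassifier):
    """Per-class Gaussian mixture densities; predict the class with the
    larger prior-weighted mixture density."""

    kind = "gmm"

    def __init__(self, g: int = 2, max_iter: int = 200, seed: int = 0,
                 reg: float = 1e-6, encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        self.g = g
        self.max_iter = max_iter
        self.seed = seed
        self.reg = reg
        self.models_: dict = {}
        self.priors_: dict = {}
        self.traces_: dict = {}

    def fit(self, x, y: LabelVector):
        x = _as_matrix(x)
        _check_two_classes(y)
        rng = np.random.default_rng(self.seed)
        lab = np.asarray(y.labels, dtype=object)
        for cls in CLASS_ORDER:
            xc = x[lab == cls]
            if xc.shape[0] <= self.g:
                raise ValueError(f"class {cls!r} has too few samples for g={self.g}")
            w, m, c, trace, _ = fit_mixture(xc, self.g, rng,
                                            max_iter=self.max_iter, reg=self.reg)
            self.models_[cls] = (w, m, c)
            self.priors_[cls] = xc.shape[0] / x.shape[0]
            self.traces_[cls] = trace
        self.training_log = self.traces_[LABEL_DIABETIC]
        return self

    def _log_density(self, x: np.ndarray, cls: str) -> np.ndarray:
        w, m, c = self.models_[cls]
        comp = np.stack([np.log(w[j]) + _log_gauss(x, m[j], c[j])
                         for j in range(len(w))], axis=1)
        return logsumexp(comp, axis=1) + np.log(self.priors_[cls])

    def predict(self, x) -> np.ndarray:
        x = _as_matrix(x)
        scores = np.stack([self._log_density(x, cls) for cls in CLASS_ORDER],
                          axis=1)
        return np.asarray(CLASS_ORDER, dtype=object)[np.argmax(scores, axis=1)]


class EMClassifier(BaseClassifier):
    """Two-component mixture on pooled (label-free) training data; the
    components are mapped to classes by majority training label, then test
    points go to the mapped component with max posterior."""

    kind = "em"

    def __init__(self, max_iter: int = 200, seed: int = 0,
                 encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, x, y: LabelVector):
        x = _as_matrix(x)
        _check_two_classes(y)
        rng = np.random.default_rng(self.seed)
        w, m, c, trace, resp = fit_mixture(x, 2, rng, max_iter=self.max_iter)
        self.weights_, self.means_, self.covs_ = w, m, c
        self.training_log = trace
        lab = np.asarray(y.labels, dtype=object)
        comp = np.argmax(resp, axis=1)
        self.component_class_ = {}
        for j in (0, 1):
            members = lab[comp == j]
            if members.size == 0:
                self.component_class_[j] = None
                continue
            dia = int((members == LABEL_DIABETIC).sum())
            self.component_class_[j] = LABEL_DIABETIC if dia * 2 >= members.size \
                else LABEL_NON_DIABETIC
        assigned = {v for v in self.component_class_.values() if v is not None}
        if len(assigned) < 2:
            only = next(iter(assigned))
            log.warning("EM components both map to %r; predictions fall back "
                        "to that class", only)
            self.component_class_ = {0: only, 1: only}
        return self

    def predict(self, x) -> np.ndarray:
        x = _as_matrix(x)
        logp = np.stack([np.log(self.weights_[j])
                         + _log_gauss(x, self.means_[j], self.covs_[j])
                         for j in (0, 1)], axis=1)
        comp = np.argmax(logp, axis=1)
        return np.asarray([self.component_class_[int(j)] for j in comp],
                          dtype=object)


# ----------------------------------------------------------------- BLDC

class BLDCClassifier(BaseClassifier):
    """Bayesian linear regression onto the class targets used as a
    discriminant: Gaussian prior (precision alpha; the bias row carries a
    small epsilon so the intercept is effectively unpenalized) and Gaussian
    noise (precision beta).  Posterior mean/covariance are closed-form;
    the predictive mean is thresholded for the decision, and the
    predictive variance 1/beta + b' X b is available per point."""

    kind = "bldc"

    def __init__(self, alpha: float = 1.0, beta: float = 10.0,
                 epsilon: float = 1e-6, encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        self.alpha = alpha
        self.beta = beta
        self.epsilon = epsilon
        self.mean_: np.ndarray | None = None
        self.cov_: np.ndarray | None = None

    def _design(self, x: np.ndarray) -> np.ndarray:
        """(l+1) x n design: feature rows plus a trailing bias row of ones."""
        return np.vstack([x.T, np.ones(x.shape[0])])

    def fit(self, x, y: LabelVector | np.ndarray):
        x = _as_matrix(x)
        targets = self.encoding.encode(y) if isinstance(y, LabelVector) \
            else np.asarray(y, dtype=float)
        b = self._design(x)
        l1 = b.shape[0]
        prior = np.full(l1, self.alpha)
        prior[-1] = self.epsilon
        a_mat = self.beta * (b @ b.T) + np.diag(prior)
        self.cov_ = np.linalg.inv(a_mat)
        self.mean_ = self.beta * (self.cov_ @ (b @ targets))
        resid = targets - self.mean_ @ b
        self.training_log = [float(resid @ resid) / len(targets)]
        return self

    def continuous(self, x) -> np.ndarray:
        return self._design(_as_matrix(x)).T @ self.mean_

    def predictive_variance(self, x) -> np.ndarray:
        b = self._design(_as_matrix(x))
        return 1.0 / self.beta + np.einsum("ij,jk,ik->i", b.T, self.cov_, b.T)

    def predict(self, x) -> np.ndarray:
        return self.encoding.decide(self.continuous(x))


# ------------------------------------------------------------------ LoR

class LoRClassifier(BaseClassifier):
    """L2-penalized logistic regression by gradient ascent from zero.

    Maximizes sum_i [y_i log p_i + (1-y_i) log(1-p_i)] - |v|^2/(2 tau^2)
    (intercept unpenalized); probabilities are logistic and strictly inside
    (0, 1); the decision threshold defaults to 0.5 with 0.48 exposed."""

    kind = "lor"

    def __init__(self, tau: float = 10.0, max_iter: int = 3000,
                 learning_rate: float = 0.5, threshold: float = 0.5,
                 grad_tol: float = 1e-6, encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        self.tau = tau
        self.max_iter = max_iter
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.grad_tol = grad_tol
        self.coef_: np.ndarray | None = None

    def fit(self, x, y: LabelVector):
        x = _as_matrix(x)
        _check_two_classes(y)
        t = y.binary(LABEL_DIABETIC).astype(float)
        m = x.shape[0]
        xb = np.hstack([np.ones((m, 1)), x])
        v = np.zeros(xb.shape[1])
        pen = np.ones_like(v) / self.tau ** 2
        pen[0] = 0.0
        # step guard: the penalty adds pen.max() to the gradient's
        # Lipschitz constant, so strong priors need a smaller step
        step = self.learning_rate / (m * (1.0 + pen.max() / m))
        self.training_log = []
        gnorm = np.inf
        for _ in range(self.max_iter):
            p = _sigmoid(xb @ v)
            ll = float(t @ np.log(p + 1e-300) + (1 - t) @ np.log(1 - p + 1e-300)) \
                - 0.5 * float(v @ (pen * v))
            self.training_log.append(ll)
            grad = xb.T @ (t - p) - pen * v
            gnorm = float(np.linalg.norm(grad))
            if gnorm < self.grad_tol:
                break
            v += step * grad
        else:
            warnings.warn(f"LoR did not converge; final |grad| = {gnorm:.3g}")
        self.coef_ = v
        return self

    def predict_proba(self, x) -> np.ndarray:
        x = _as_matrix(x)
        return _sigmoid(np.hstack([np.ones((x.shape[0], 1)), x]) @ self.coef_)

    def continuous(self, x) -> np.ndarray:
        return self.predict_proba(x)

    def predict(self, x) -> np.ndarray:
        return np.where(self.predict_proba(x) >= self.threshold,
                        LABEL_DIABETIC, LABEL_NON_DIABETIC)


# ------------------------------------------------------------------ SDC

class SDCClassifier(BaseClassifier):
    """Softmax discriminant: class score log sum_j exp(-lambda |v - v_j|^2)
    over that class's training samples, log-sum-exp stabilized.  Exact
    score ties go to the lower class index (diabetic first)."""

    kind = "sdc"

    def __init__(self, lam: float = 0.5, encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        self.lam = lam
        self.train_: dict = {}

    def fit(self, x, y: LabelVector):
        x = _as_matrix(x)
        lab = np.asarray(y.labels, dtype=object)
        for cls in CLASS_ORDER:
            xc = x[lab == cls]
            if xc.shape[0] == 0:
                raise ValueError(f"empty class {cls!r}")
            self.train_[cls] = xc
        self.training_log = []
        return self

    def scores(self, x) -> np.ndarray:
        x = _as_matrix(x)
        out = np.empty((x.shape[0], len(CLASS_ORDER)))
        for ci, cls in enumerate(CLASS_ORDER):
            z = self.train_[cls]
            d2 = ((x[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
            out[:, ci] = logsumexp(-self.lam * d2, axis=1)
        return out

    def predict(self, x) -> np.ndarray:
        sc = self.scores(x)
        return np.asarray(CLASS_ORDER, dtype=object)[np.argmax(sc, axis=1)]


# ------------------------------------------------------------------ SVM

def kernel_eval(kind: str, x1, x2, gamma: float = 1.0, degree: int = 2) -> float:
    """Kernel values: linear x1.x2; poly (gamma x1.x2 + 1)^degree; RBF
    exp(-gamma |x1-x2|^2) with gamma = 1/(2 sigma)^2 tying the printed
    gamma to the (2 sigma)^2 form."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if kind == "linear":
        return float(x1 @ x2)
    if gamma <= 0:
        raise ValueError("gamma must be > 0 for poly/rbf")
    if kind == "poly":
        return float((gamma * (x1 @ x2) + 1.0) ** degree)
    if kind == "rbf":
        return float(np.exp(-gamma * ((x1 - x2) ** 2).sum()))
    raise ValueError(f"unknown kernel {kind!r}")


class SVMClassifier(BaseClassifier):
    """Soft-margin SVM (dual box [0, C]) with linear / polynomial / RBF
    kernels, solved by scikit-learn's SMO backend.

    ``reduce_supports`` applies the k-means support-thinning scheme: 2
    clusters, 3 randomly sampled points per cluster, retrain on those 6
    points (a severe approximation; off by default)."""

    kind = "svm"

    def __init__(self, kernel: str = "rbf", C: float = 1.0,
                 gamma: "float | str" = 100.0, degree: int = 2,
                 reduce_supports: bool = False, seed: int = 0,
                 tol: float = 1e-6, encoding: TargetEncoding | None = None):
        super().__init__(encoding)
        if kernel not in ("linear", "poly", "rbf"):
            raise ValueError(f"unknown kernel {kernel!r}")
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.reduce_supports = reduce_supports
        self.seed = seed
        self.tol = tol
        self.svc_: SVC | None = None

    def _make_svc(self) -> SVC:
        kw = dict(C=self.C, kernel=self.kernel, tol=self.tol)
        if self.kernel == "poly":
            kw.update(gamma=self.gamma, degree=self.degree, coef0=1.0)
        elif self.kernel == "rbf":
            kw.update(gamma=self.gamma)
        return SVC(**kw)

    def fit(self, x, y: LabelVector):
        x = _as_matrix(x)
        _check_two_classes(y)
        z = np.where(np.asarray(y.labels, dtype=object) == LABEL_DIABETIC, 1, -1)
        svc = self._make_svc().fit(x, z)
        if self.reduce_supports:
            rng = np.random.default_rng(self.seed)
            km = KMeans(n_clusters=2, n_init=5,
                        random_state=self.seed).fit(x)
            keep: list[int] = []
            for c in (0, 1):
                members = np.flatnonzero(km.labels_ == c)
                take = min(3, members.size)
                keep.extend(rng.choice(members, size=take, replace=False))
            keep = sorted(keep)
            if len(set(z[keep])) == 2:
                svc = self._make_svc().fit(x[keep], z[keep])
            else:
                log.warning("support reduction kept a single class; "
                            "full-data model retained")
        self.svc_ = svc
        self.training_log = []
        return self

    def decision_function(self, x) -> np.ndarray:
        return self.svc_.decision_function(_as_matrix(x))

    def dual_objective(self, x, y: LabelVector) -> float:
        """Value of the dual objective at the fitted multipliers."""
        x = _as_matrix(x)
        z = np.where(np.asarray(y.labels, dtype=object) == LABEL_DIABETIC, 1, -1)
        sv = self.svc_.support_
        alpha_z = self.svc_.dual_coef_[0]           # alpha_i * z_i
        alpha = np.abs(alpha_z)
        gamma = self.svc_._gamma if isinstance(self.gamma, str) else self.gamma
        k = np.array([[kernel_eval(self.kernel, x[i], x[j], gamma,
                                   self.degree) for j in sv] for i in sv])
        return float(alpha.sum() - 0.5 * alpha_z @ k @ alpha_z)

    def predict(self, x) -> np.ndarray:
        z = self.svc_.predict(_as_matrix(x))
        return np.where(z > 0, LABEL_DIABETIC, LABEL_NON_DIABETIC)


# ------------------------------------------------------------- factory

def make_classifier(name: str, encoding: TargetEncoding | None = None,
                    **overrides) -> BaseClassifier:
    """Construct one of the ten classifiers by short name with the printed
    hyperparameter defaults (SVM: linear C=0.85; poly C=0.76, gamma=10;
    rbf C=1, gamma=100)."""
    name = name.replace("-", "_")
    table: dict[str, tuple[type, dict]] = {
        "nlr": (NLRClassifier, {}),
        "lr": (LRClassifier, {}),
        "gmm": (GMMClassifier, {}),
        "em": (EMClassifier, {}),
        "bldc": (BLDCClassifier, {}),
        "lor": (LoRClassifier, {}),
        "sdc": (SDCClassifier, {}),
        "svm_l": (SVMClassifier, {"kernel": "linear", "C": 0.85}),
        "svm_poly": (SVMClassifier, {"kernel": "poly", "C": 0.76, "gamma": 10.0}),
        "svm_rbf": (SVMClassifier, {"kernel": "rbf", "C": 1.0, "gamma": 100.0}),
    }
    if name not in table:
        raise ValueError(f"unknown classifier {name!r}")
    cls, defaults = table[name]
    return cls(encoding=encoding, **{**defaults, **overrides})


CLASSIFIER_NAMES = ("nlr", "lr", "gmm", "em", "bldc",
                    "lor", "sdc", "svm_l", "svm_poly", "svm_rbf")


def classify(model: BaseClassifier, x, encoding: TargetEncoding | None = None
             ) -> np.ndarray:
    """Predict labels, validating the target-separation constraint first."""
    enc = encoding or model.encoding
    if abs(enc.t_dia - enc.t_nd) < 0.5:
        raise ValueError("target encoding violates the 0.5 separation rule")
    return model.predict(x)
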