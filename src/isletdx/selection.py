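"""Swarm feature selectors: Elephant Herding Optimization and the
Dragonfly Algorithm, plus the Welch t-test audit of selected features.

Both selectors search continuous positions in [0,1]^F, decode a position to
the k top-weighted features and score it with the shared Fisher-ratio
filter fitness (see :mod:`isletdx.fitness`).  An elitist memory keeps the
best mask ever evaluated, so best-fitness traces are monotone.

EHO (single-herd form): followers move toward the fittest member,
y <- y + alpha * (y_best - y) * r with one scalar r per follower; the
fittest member is reset to beta * herd centre; the least fit member is
re-drawn per dimension as y_min + (y_max - y_min + 1) * rand, kept in its
literal printed form and then clamped into bounds.

DOA: classic five-force dynamics (separation, alignment, cohesion,
attraction to the best-so-far "food", diversion from the worst-so-far
"enemy") with inertia on the step vector.  The printed enemy term is
literally (enemy + self); the canonical (enemy - self) form is available
behind ``da_literal_enemy=False``.  The default neighborhood is global
(static swarm); a finite radius with a random-walk fallback for isolated
flies is config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import LabelVector, LABEL_DIABETIC
from .fitness import fisher_ratios, decode_top_k, subset_fitness


@dataclass
class FeatureMask:
    selected: list[int]
    k: int
    source_method: str

    def __post_init__(self) -> None:
        self.selected = sorted(int(i) for i in self.selected)
        if len(self.selected) != self.k:
            raise ValueError("|selected| != k")
        if len(set(self.selected)) != self.k:
            raise ValueError("duplicate feature indices")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return values[np.asarray(self.selected, dtype=int)]


@dataclass
class EHOParams:
    alpha: float = 0.5
    # the leader reset beta * centre biases toward the origin corner of a
    # [0, 1] mask space when beta is small; 0.5 balances that bias against
    # the diversity the reset provides
    beta: float = 0.5
    n_elephants: int = 20
    iterations: int = 100
    bounds: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must be in [0, 1]")
        if self.n_elephants < 2:
            raise ValueError("need >= 2 elephants")


@dataclass
class DOAParams:
    n_flies: int = 20
    iterations: int = 100
    # linear decay endpoints (start, end) over the iteration budget; the
    # separation weight keeps a floor so the swarm keeps sampling around
    # the food instead of collapsing onto it
    s_weight: tuple[float, float] = (0.3, 0.1)
    a_weight: tuple[float, float] = (0.1, 0.0)
    c_weight: tuple[float, float] = (0.1, 0.0)
    h_weight: tuple[float, float] = (1.0, 0.5)
    d_weight: tuple[float, float] = (0.1, 0.0)
    inertia: tuple[float, float] = (0.9, 0.4)
    neighborhood_radius: float | None = None   # None = global neighborhood
    step_clamp: float = 0.1                    # fraction of the bound range
    # the printed enemy term (enemy + self) drives coordinates into the
    # upper bound clamp; the canonical (enemy - self) diversion is default
    da_literal_enemy: bool = False
    bounds: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        for w in (self.s_weight, self.a_weight, self.c_weight,
                  self.h_weight, self.d_weight):
            if min(w) < 0:
                raise ValueError("force weights must be non-negative")
        if not (0 <= min(self.inertia) and max(self.inertia) <= 1):
            raise ValueError("inertia must stay in [0, 1]")


# ----------------------------------------------------------------- EHO ops

def eho_update_position(y_old: np.ndarray, y_best: np.ndarray, alpha: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Follower update y_old + alpha * (y_best - y_old) * r, scalar r."""
    r = rng.random()
    return y_old + alpha * (y_best - y_old) * r


def eho_best_update(positions: np.ndarray, beta: float) -> np.ndarray:
    """New position of the herd's best member: beta * coordinate-wise mean."""
    if positions.shape[0] < 1:
        raise ValueError("need >= 1 elephant")
    return beta * positions.mean(axis=0)


def eho_worst_replace(y_min: float, y_max: float,
                      rng: np.random.Generator) -> float:
    """Literal worst replacement y_min + (y_max - y_min + 1) * rand, then
    clamped into [y_min, y_max]."""
    if y_min > y_max:
        raise ValueError("y_min must be <= y_max")
    raw = y_min + (y_max - y_min + 1.0) * rng.random()
    return min(max(raw, y_min), y_max)


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)


def eho_optimize(objective, n_dims: int, params: EHOParams,
                 maximize: bool = True) -> SwarmResult:
    """Single-herd EHO on a black-box objective with elitist memory."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.bounds
    sign = 1.0 if maximize else -1.0

    def f(p):
        return sign * objective(p)

    n = params.n_elephants
    pos = rng.uniform(lo, hi, size=(n, n_dims))
    fit = np.array([f(p) for p in pos])
    bi = int(np.argmax(fit))
    best_pos, best_fit = pos[bi].copy(), float(fit[bi])
    trace = [best_fit]
    for _ in range(params.iterations):
        bi = int(np.argmax(fit))
        wi = int(np.argmin(fit))
        leader = pos[bi].copy()
        centre_target = eho_best_update(pos, params.beta)
        for i in range(n):
            if i == bi:
                continue
            pos[i] = np.clip(eho_update_position(pos[i], leader,
                                                 params.alpha, rng), lo, hi)
        pos[bi] = np.clip(centre_target, lo, hi)
        if wi != bi:
            pos[wi] = np.array([eho_worst_replace(lo, hi, rng)
                                for _ in range(n_dims)])
        fit = np.array([f(p) for p in pos])
        ci = int(np.argmax(fit))
        if fit[ci] > best_fit:
            best_pos, best_fit = pos[ci].copy(), float(fit[ci])
        trace.append(best_fit)
    return SwarmResult(best_pos, sign * best_fit, [sign * t for t in trace])


def eho_select(x, y: LabelVector, k: int,
               params: EHOParams | None = None) -> FeatureMask:
    """Select ``k`` features from a (Reduced)Matrix with EHO."""
    if params is None:
        params = EHOParams()
    values = x.values
    if k >= values.shape[0]:
        raise ValueError("k must be smaller than the feature count")
    ratios = fisher_ratios(values, y)
    res = eho_optimize(lambda p: subset_fitness(p, ratios, k),
                       values.shape[0], params)
    return FeatureMask(list(decode_top_k(res.best_position, k)), k, "eho")


# ----------------------------------------------------------------- DOA ops

def doa_forces(fly_index: int, positions: np.ndarray, velocities: np.ndarray,
               food: np.ndarray, enemy: np.ndarray, params: DOAParams,
               neighbors: np.ndarray | None = None):
    """The five force vectors (Se, Ag, Co, H, D) for one fly.

    With no neighbors: Se = 0, Ag = the fly's own velocity, Co = 0
    (empty-sum conventions of the original algorithm).
    """
    x = positions[fly_index]
    if neighbors is None:
        neighbors = _neighbors(fly_index, positions, params)
    if neighbors.size:
        nb = positions[neighbors]
        se = -(x - nb).sum(axis=0)
        ag = velocities[neighbors].mean(axis=0)
        co = nb.mean(axis=0) - x
    else:
        se = np.zeros_like(x)
        ag = velocities[fly_index].copy()
        co = np.zeros_like(x)
    h = food - x
    d = enemy + x if params.da_literal_enemy else enemy - x
    return se, ag, co, h, d


def _neighbors(i: int, positions: np.ndarray, params: DOAParams) -> np.ndarray:
    n = positions.shape[0]
    others = np.array([j for j in range(n) if j != i])
    if params.neighborhood_radius is None:
        return others
    dist = np.linalg.norm(positions[others] - positions[i], axis=1)
    return others[dist <= params.neighborhood_radius]


def _schedule(pair: tuple[float, float], frac: float) -> float:
    return pair[0] + (pair[1] - pair[0]) * frac


def doa_step(positions: np.ndarray, velocities: np.ndarray, food: np.ndarray,
             enemy: np.ndarray, params: DOAParams, frac: float,
             rng: np.random.Generator) -> None:
    """One synchronous swarm update, in place.

    delta-K <- s*Se + a*Ag + c*Co + h*H + d*D + omega*delta-K, then
    K <- K + delta-K with a step clamp and a bound clamp.  ``frac`` in
    [0, 1] advances the linear weight schedules.  Flies with no neighbors
    under a finite radius take a small random walk instead (canonical
    convention).
    """
    s = _schedule(params.s_weight, frac)
    a = _schedule(params.a_weight, frac)
    c = _schedule(params.c_weight, frac)
    h = _schedule(params.h_weight, frac)
    d = _schedule(params.d_weight, frac)
    w = _schedule(params.inertia, frac)
    lo, hi = params.bounds
    n = positions.shape[0]
    new_v = np.empty_like(velocities)
    walkers = []
    for i in range(n):
        nbrs = _neighbors(i, positions, params)
        if params.neighborhood_radius is not None and nbrs.size == 0:
            walkers.append(i)
            new_v[i] = 0.0
            continue
        se, ag, co, hh, dd = doa_forces(i, positions, velocities, food,
                                        enemy, params, neighbors=nbrs)
        # per-fly 2*rand factors on every force weight (canonical DA);
        # the randomized attraction keeps the swarm sampling around the
        # food instead of collapsing onto it deterministically
        rs, ra, rc, rh, rd_ = 2.0 * rng.random(5)
        step = (s * rs * se + a * ra * ag + c * rc * co + h * rh * hh
                + d * rd_ * dd + w * velocities[i])
        vmax = params.step_clamp * (hi - lo)
        new_v[i] = np.clip(step, -vmax, vmax)
    velocities[:] = new_v
    positions += velocities
    for i in walkers:
        positions[i] += rng.normal(0.0, 0.05 * (hi - lo), size=positions.shape[1])
    np.clip(positions, lo, hi, out=positions)


def doa_optimize(objective, n_dims: int, params: DOAParams,
                 maximize: bool = True) -> SwarmResult:
    """Dragonfly dynamics on a black-box objective; the food memory is the
    elitist best-so-far, the enemy memory the worst-so-far."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.bounds
    sign = 1.0 if maximize else -1.0

    def f(p):
        return sign * objective(p)

    n = params.n_flies
    pos = rng.uniform(lo, hi, size=(n, n_dims))
    vel = np.zeros_like(pos)
    fit = np.array([f(p) for p in pos])
    bi, wi = int(np.argmax(fit)), int(np.argmin(fit))
    food, food_fit = pos[bi].copy(), float(fit[bi])
    enemy, enemy_fit = pos[wi].copy(), float(fit[wi])
    trace = [food_fit]
    iters = max(params.iterations, 1)
    for t in range(params.iterations):
        doa_step(pos, vel, food, enemy, params, t / iters, rng)
        fit = np.array([f(p) for p in pos])
        bi, wi = int(np.argmax(fit)), int(np.argmin(fit))
        if fit[bi] > food_fit:
            food, food_fit = pos[bi].copy(), float(fit[bi])
        if fit[wi] < enemy_fit:
            enemy, enemy_fit = pos[wi].copy(), float(fit[wi])
        trace.append(food_fit)
    return SwarmResult(food, sign * food_fit, [sign * t for t in trace])


def doa_select(x, y: LabelVector, k: int,
               params: DOAParams | None = None) -> FeatureMask:
    """Select ``k`` features from a (Reduced)Matrix with the DA."""
    if params is None:
        params = DOAParams()
    values = x.values
    if k >= values.shape[0]:
        raise ValueError("k must be smaller than the feature count")
    ratios = fisher_ratios(values, y)
    res = doa_optimize(lambda p: subset_fitness(p, ratios, k),
                       values.shape[0], params)
    return FeatureMask(list(decode_top_k(res.best_position, k)), k, "doa")


# -------------------------------------------------------------- p-value audit

def feature_pvalues(x, y: LabelVector) -> tuple[np.ndarray, float]:
    """Per-feature Welch t-test p-values and their mean.

    The single summary scalar per method/class follows the mean-of-p
    convention.  A feature with zero variance in both classes has t = 0 /
    undefined and gets p = 1 by convention.
    """
    mask = y.binary(LABEL_DIABETIC).astype(bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both classes need >= 2 samples")
    a, b = x.values[:, mask], x.values[:, ~mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)
    return p, float(p.mean())
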