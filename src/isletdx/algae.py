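"""Artificial Algae Algorithm: a colony-based stochastic optimizer, and its
use as a selection-based dimensionality reducer.

Each colony is a candidate position with a biomass H (Monod-style growth,
mu_max = 1: H <- mu * H with mu from min-max normalized fitness mapped to
[0.5, 1]) and a starvation level.  Colonies swim helically toward fitter
colonies: three randomly chosen coordinates move toward a tournament-chosen
target, scaled by (shear Delta - friction surface tau(H)), where tau is the
surface area of a hemisphere of the colony's volume.  Moves are greedy
(kept only when fitness improves) and each colony spends an energy budget
per iteration, paying half the loss for a successful move.  Per iteration
the smallest colony's cells are overwritten by the largest's (replication),
the hungriest colony may adapt toward the biggest, and an elitist memory
keeps the best position ever seen, so the best-fitness trace is monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import LabelVector
from .fitness import fisher_ratios, decode_top_k, subset_fitness
from .reduction import ReducedMatrix


@dataclass
class AAAParams:
    n_colonies: int = 20
    iterations: int = 100
    shear_delta: float = 2.0
    energy_loss: float = 0.3
    # adaptation blends a whole position toward the biggest colony; applied
    # too often it collapses swarm diversity in high-dimensional spaces
    adaptation_prob: float = 0.2
    bounds: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_colonies < 3:
            raise ValueError("need at least 3 colonies")
        if not 0 <= self.adaptation_prob <= 1:
            raise ValueError("adaptation_prob must be in [0, 1]")
        if self.energy_loss <= 0:
            raise ValueError("energy_loss must be > 0")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("invalid bounds")


def friction_surface(biomass: float) -> float:
    """Hemisphere surface area tau = 2 pi (3 H / 4 pi)^(2/3) of a colony of
    volume ``biomass``."""
    if biomass < 0:
        raise ValueError("biomass must be >= 0")
    return 2.0 * math.pi * (3.0 * biomass / (4.0 * math.pi)) ** (2.0 / 3.0)


def monod_growth(biomass: float, mu: float) -> float:
    """New biomass mu * H (mu in [0, 1], mu_max = 1)."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    return mu * biomass


def growth_rates(fitness: np.ndarray) -> np.ndarray:
    """Min-max normalize fitness to [0.5, 1]; the fittest colony gets 1."""
    lo, hi = float(np.min(fitness)), float(np.max(fitness))
    if hi == lo:
        return np.ones_like(fitness, dtype=float)
    return 0.5 + 0.5 * (fitness - lo) / (hi - lo)


def helical_move(position: np.ndarray, target: np.ndarray, delta: float,
                 tau: float, bounds: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Move exactly three distinct random coordinates toward ``target``.

    One coordinate moves linearly (factor p in [-1, 1]), one by cos(alpha)
    and one by sin(beta) with alpha, beta in [0, 2 pi]; the step is scaled
    by (delta - tau).  For D < 3 the available subset of the three update
    forms is used.  The result is clamped into bounds.
    """
    d = position.shape[0]
    out = position.astype(float).copy()
    scale = delta - tau
    n_dims = min(3, d)
    dims = rng.choice(d, size=n_dims, replace=False)
    factors = [rng.uniform(-1.0, 1.0),
               math.cos(rng.uniform(0.0, 2.0 * math.pi)),
               math.sin(rng.uniform(0.0, 2.0 * math.pi))]
    for dim, f in zip(dims, factors[:n_dims]):
        out[dim] += (target[dim] - out[dim]) * scale * f
    return np.clip(out, bounds[0], bounds[1])


def starvation_update(start: float, max_t: float, rng: np.random.Generator) -> float:
    """Start <- Start + (max_t - Start) * rand; applied to colonies that
    failed to improve this iteration."""
    return start + (max_t - start) * rng.random()


def evolutionary_step(positions: np.ndarray, biomass: np.ndarray,
                      rng: np.random.Generator | None = None) -> tuple[int, int, int]:
    """One replication event: a cell (coordinate) of the largest colony
    replaces the corresponding cell of the smallest, in place.

    Ranking is by biomass; ties break to the lowest colony index for
    "largest" (and the lowest remaining index for "smallest").  The
    replicated dimension is chosen uniformly at random (deterministically
    the first dimension when no generator is supplied).  Replicating whole
    positions instead collapses the swarm onto one point within tens of
    iterations, so replication is per-cell.  Returns
    (smallest, largest, dimension).
    """
    if positions.shape[0] < 2:
        raise ValueError("need >= 2 colonies")
    largest = int(np.argmax(biomass))          # argmax takes the first max
    order = np.argsort(biomass, kind="stable")
    smallest = int(order[0]) if order[0] != largest else int(order[1])
    dim = int(rng.integers(positions.shape[1])) if rng is not None else 0
    positions[smallest, dim] = positions[largest, dim]
    return smallest, largest, dim


@dataclass
class AAAResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)
    n_evals: int = 0


def aaa_optimize(objective: Callable[[np.ndarray], float], n_dims: int,
                 params: AAAParams, maximize: bool = True) -> AAAResult:
    """Run the algae optimizer on a black-box objective."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.bounds
    sign = 1.0 if maximize else -1.0

    def f(x: np.ndarray) -> float:
        return sign * objective(x)

    n = params.n_colonies
    pos = rng.uniform(lo, hi, size=(n, n_dims))
    fit = np.array([f(p) for p in pos])
    n_evals = n
    biomass = np.ones(n)
    starv = np.zeros(n)

    best_i = int(np.argmax(fit))
    best_pos, best_fit = pos[best_i].copy(), float(fit[best_i])
    trace = [best_fit]

    for _ in range(params.iterations):
        mu = growth_rates(fit)
        biomass = np.array([monod_growth(h, m) for h, m in zip(biomass, mu)])
        tau = np.array([friction_surface(h) for h in biomass])
        improved = np.zeros(n, dtype=bool)
        for i in range(n):
            energy = 1.0
            while energy > 0:
                a, b = rng.choice(n, size=2, replace=False)
                j = a if fit[a] >= fit[b] else b
                cand = helical_move(pos[i], pos[j], params.shear_delta,
                                    tau[i], params.bounds, rng)
                cf = f(cand)
                n_evals += 1
                if cf > fit[i]:
                    pos[i], fit[i] = cand, cf
                    improved[i] = True
                    energy -= params.energy_loss / 2
                else:
                    energy -= params.energy_loss
        # starvation of non-improvers drifts toward the current max fitness,
        # used only to rank hunger for the adaptation step
        max_t = float(np.max(fit))
        for i in np.flatnonzero(~improved):
            starv[i] = starvation_update(starv[i], max_t, rng)
        if rng.random() < params.adaptation_prob:
            hungry = int(np.argmax(starv))
            big = int(np.argmax(biomass))
            if hungry != big:
                pos[hungry] = pos[hungry] + (pos[big] - pos[hungry]) * rng.random()
                pos[hungry] = np.clip(pos[hungry], lo, hi)
                fit[hungry] = f(pos[hungry])
                n_evals += 1
        changed, _, _ = evolutionary_step(pos, biomass, rng)
        fit[changed] = f(pos[changed])
        n_evals += 1
        # elitism as memory: the best position ever seen is recorded (and
        # returned) but not reinjected, which would homogenize the swarm
        cur_best = int(np.argmax(fit))
        if fit[cur_best] > best_fit:
            best_pos, best_fit = pos[cur_best].copy(), float(fit[cur_best])
        trace.append(best_fit)

    return AAAResult(best_pos, sign * best_fit,
                     [sign * t for t in trace], n_evals)


def aaa_reduce(x, y: LabelVector, d_out: int, params: AAAParams | None = None
               ) -> tuple[ReducedMatrix, np.ndarray]:
    """Select ``d_out`` genes by maximizing mean Fisher ratio with AAA.

    ``x`` may be an ExpressionMatrix or a ReducedMatrix; positions live in
    [0, 1]^G and decode to the d_out top-weighted genes.
    """
    if params is None:
        params = AAAParams()
    values = x.values
    g = values.shape[0]
    if d_out >= g:
        raise ValueError("d_out must be smaller than the gene count")
    ratios = fisher_ratios(values, y)
    res = aaa_optimize(lambda p: subset_fitness(p, ratios, d_out), g, params)
    idx = decode_top_k(res.best_position, d_out)
    ids = [x.gene_ids[i] for i in idx] if hasattr(x, "gene_ids") \
        else [x.feature_ids[i] for i in idx]
    rm = ReducedMatrix(ids, list(x.sample_ids), values[idx], "aaa")
    return rm, idx
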