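"""Benchmark the three swarm optimizers on the 10-D sphere function.

Each optimizer minimizes sum(x^2) on [-5, 5]^10 from a random population
of 20; the score is the best value found after 100 iterations relative to
the initial population's median (smaller is better, 0 is the optimum).
"""

import numpy as np

from isletdx import AAAParams, DOAParams, EHOParams, aaa_optimize
from isletdx.selection import doa_optimize, eho_optimize

sphere = lambda v: float((v ** 2).sum())  # noqa: E731

for name, optimize, make_params in [
        ("artificial algae", aaa_optimize,
         lambda s: AAAParams(bounds=(-5, 5), seed=s)),
        ("elephant herding", eho_optimize,
         lambda s: EHOParams(bounds=(-5, 5), seed=s)),
        ("dragonfly", doa_optimize,
         lambda s: DOAParams(bounds=(-5, 5), seed=s))]:
    ratios = []
    for seed in range(10):
        res = optimize(sphere, 10, make_params(seed), maximize=False)
        init = np.random.default_rng(seed).uniform(-5, 5, (20, 10))
        ratios.append(res.best_fitness / np.median((init ** 2).sum(axis=1)))
    print(f"{name:18s} median best/initial-median over 10 seeds: "
          f"{np.median(ratios):.2e}")
# All three should land far below 1e-2, i.e. >99% improvement over the
# initial population.
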