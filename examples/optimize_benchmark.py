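"""Minimize two benchmark objectives with the Fire Hawk Optimizer.

The history is the best objective value found so far, so it can only
decrease; the sphere optimum is 0 at the origin, the shifted quadratic's
optimum is x = 2.
"""

import numpy as np

from nutrihawk import FHOConfig, SearchSpace, minimize

sphere = lambda x: float((x ** 2).sum())
space = SearchSpace(np.full(5, -5.0), np.full(5, 5.0))
res = minimize(sphere, space, FHOConfig(pop_size=50, max_iters=300, seed=0))
print("5-D sphere on [-5, 5]^5")
print(f"  best fitness {res.best_fitness:.3e} (true optimum 0)")
print("  history at iters 1/50/150/300:",
      [f"{res.history[i]:.2e}" for i in (0, 49, 149, 299)])

quad = lambda x: float((x[0] - 2.0) ** 2)
res1 = minimize(quad, SearchSpace(np.array([0.0]), np.array([4.0])),
                FHOConfig(pop_size=20, max_iters=100, seed=0))
print(f"1-D (x-2)^2 on [0, 4]: best x = {res1.best_position[0]:.5f} (optimum 2)")
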