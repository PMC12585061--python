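"""Harmony Search with Opposition-Based Learning on a convex benchmark.

Optimizes the 5-dimensional sphere over [-5, 5]^5 at the standard
settings (HMCR 0.9, PAR 0.3, HMS 30, 50 iterations, opposition on) and
prints the best point found plus the effect of opposition events.
"""

from lungsound.hsobl import Dimension, HSConfig, SearchSpace, optimize

space = SearchSpace([Dimension(f"x{i}", -5.0, 5.0) for i in range(5)])
result = optimize(space, lambda p: sum(v * v for v in p.values()),
                  HSConfig(seed=0))

print(f"best fitness: {result.best.fitness:.2e} at "
      f"{[round(float(v), 3) for v in result.best.vector]}")
opposition_events = sum(r["opposition"] for r in result.history)
print(f"iterations: {len(result.history)}, opposition events: {opposition_events}")
print(f"best-so-far trace (every 10th): "
      f"{[round(r['best_fitness'], 4) for r in result.history[::10]]}")
print("-> fitness is monotonically non-increasing; the optimum (0) is approached")
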