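"""Incremental fitness evaluation for single-cell toggles.

The optimizer repeatedly asks "what happens to the objective if this one
cell is protected / unprotected?" over tens of thousands of candidate
cells.  Re-evaluating the full objective per candidate would cost O(grid)
each; this evaluator maintains three running sums and two auxiliary
rasters so that

* the fitness change of toggling any single cell is available for *all*
  cells at once as a vectorized array, and
* applying a toggle costs O(n^2) for window side n.

State maintained for a current assignment ``x``:

* ``p``    — per-cell count of protected cells in the n×n window
             (exact integer arithmetic);
* ``w_inv``— per-cell window sum of ``x * inv_d`` where ``inv_d`` is the
             reciprocal configurable-count raster;
* running sums of eco, dev and neighborhood-density contributions.

Toggling cell c changes ``p`` and ``w_inv`` only inside c's own window,
and changes the density sum by a closed-form amount derived from ``p``
and ``w_inv`` at c.
"""

from __future__ import annotations

import numpy as np

from .model import CompactnessSpec, SuitabilityGrid, Weights, _window_sums


class IncrementalEvaluator:
    """Mutable evaluation state for one candidate assignment."""

    __slots__ = ("grid", "w", "q", "n", "half", "inv_d", "x", "p", "w_inv",
                 "eco_sum", "dev_sum", "com_sum", "_site_gain")

    def __init__(self, grid: SuitabilityGrid, w: Weights, spec: CompactnessSpec,
                 q: int, x: np.ndarray):
        self.grid = grid
        self.w = w
        self.q = q
        self.n = spec.n
        self.half = spec.half
        _, self.inv_d = grid.window_config(spec.n)
        self.x = np.asarray(x).astype(bool).copy()
        xf = self.x.astype(np.float64)
        self.p = np.rint(_window_sums(xf, spec.n)).astype(np.int64)
        self.w_inv = _window_sums(xf * self.inv_d, spec.n)
        self.eco_sum = float(grid.eco[self.x].sum())
        self.dev_sum = float(grid.dev[self.x].sum())
        self.com_sum = float((self.p * self.inv_d)[self.x].sum())
        # per-cell site contribution to the fitness numerator
        self._site_gain = (w.w1 * grid.eco - w.w2 * grid.dev) / q

    def fitness(self) -> float:
        w, q = self.w, self.q
        return (w.w1 * self.eco_sum / q
                + w.w2 * (1.0 - self.dev_sum / q)
                + w.w3 * self.com_sum / q)

    def _window(self, r: int, c: int):
        h = self.half
        nr, nc = self.x.shape
        return (slice(max(r - h, 0), min(r + h + 1, nr)),
                slice(max(c - h, 0), min(c + h + 1, nc)))

    def add(self, r: int, c: int) -> None:
        """Protect cell (r, c); it must currently be unprotected."""
        inv = self.inv_d[r, c]
        # new cell's own density + one extra neighbor for each protected
        # cell already inside its window
        self.com_sum += (self.p[r, c] + 1) * inv + self.w_inv[r, c]
        self.eco_sum += self.grid.eco[r, c]
        self.dev_sum += self.grid.dev[r, c]
        win = self._window(r, c)
        self.p[win] += 1
        self.w_inv[win] += inv
        self.x[r, c] = True

    def remove(self, r: int, c: int) -> None:
        """Unprotect cell (r, c); it must currently be protected."""
        inv = self.inv_d[r, c]
        self.com_sum -= self.p[r, c] * inv + (self.w_inv[r, c] - inv)
        self.eco_sum -= self.grid.eco[r, c]
        self.dev_sum -= self.grid.dev[r, c]
        win = self._window(r, c)
        self.p[win] -= 1
        self.w_inv[win] -= inv
        self.x[r, c] = False

    def delta_add(self) -> np.ndarray:
        """Fitness change of protecting each cell (meaningful where x is False)."""
        w3q = self.w.w3 / self.q
        return self._site_gain + w3q * ((self.p + 1) * self.inv_d + self.w_inv)

    def delta_remove(self) -> np.ndarray:
        """Fitness change of unprotecting each cell (meaningful where x is True)."""
        w3q = self.w.w3 / self.q
        return -self._site_gain - w3q * (self.p * self.inv_d + self.w_inv - self.inv_d)

    def delta_add_at(self, r: int, c: int) -> float:
        w3q = self.w.w3 / self.q
        return float(self._site_gain[r, c]
                     + w3q * ((self.p[r, c] + 1) * self.inv_d[r, c] + self.w_inv[r, c]))

    def delta_remove_at(self, r: int, c: int) -> float:
        w3q = self.w.w3 / self.q
        inv = self.inv_d[r, c]
        return float(-self._site_gain[r, c]
                     - w3q * (self.p[r, c] * inv + self.w_inv[r, c] - inv))
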