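"""Deterministic baselines for the zoning problem."""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .iabc import _top_q_order
from .model import Solution, SuitabilityGrid, Weights, site_score

__all__ = ["density_slice"]


def density_slice(grid: SuitabilityGrid, w: Weights, q: int) -> Solution:
    """Density-slicing baseline: threshold the site-score layer so that
    exactly q configurable cells pass.

    Equivalent to taking the top-q configurable cells by
    ``(w1*Eco + w2*(1-Dev))/(w1+w2)``; the implied threshold is the q-th
    largest score.  Ties at the threshold are broken by lowest row-major
    index, so the pass is fully deterministic.  This is optimal for the
    site-only objective (w3 = 0) but ignores compactness.
    """
    if q > grid.n_configurable:
        raise ConfigurationError(
            f"quota {q} exceeds configurable cell count {grid.n_configurable}")
    ordered = _top_q_order(grid, site_score(grid, w))
    x = np.zeros(grid.shape, dtype=bool)
    x.ravel()[ordered[:q]] = True
    return Solution(x)
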