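"""Solution quality and stability diagnostics.

Covers three post-hoc analyses: overlay agreement against a reference
zoning (e.g. a known optimum), cell-wise overlap across repeated
stochastic runs, and land-use composition of a zoning against a
categorical map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InstanceError
from .model import Solution

__all__ = ["OverlayReport", "overlay_match", "run_overlap", "landuse_stats"]


@dataclass(frozen=True)
class OverlayReport:
    """Agreement of a solution with a reference mask, counted over the Q
    protected cells."""

    matched_count: int
    nonmatched_count: int

    @property
    def q(self) -> int:
        return self.matched_count + self.nonmatched_count

    @property
    def nonmatched_pct(self) -> float:
        return 100.0 * self.nonmatched_count / self.q


def _as_x(sol) -> np.ndarray:
    x = sol.x if isinstance(sol, Solution) else np.asarray(sol)
    return x.astype(bool, copy=False)


def overlay_match(sol, reference: np.ndarray, q: int) -> OverlayReport:
    """Count protected cells inside / outside a reference boolean mask."""
    x = _as_x(sol)
    reference = np.asarray(reference).astype(bool)
    if x.shape != reference.shape:
        raise InstanceError(
            f"solution shape {x.shape} != reference shape {reference.shape}")
    if int(x.sum()) != q:
        raise InstanceError(f"solution protects {int(x.sum())} cells, expected {q}")
    matched = int((x & reference).sum())
    return OverlayReport(matched_count=matched, nonmatched_count=q - matched)


def run_overlap(solutions: Sequence, q: int) -> tuple[float, np.ndarray]:
    """Stability of repeated runs: percentage of Q protected in *every* run.

    Returns ``(overlap_pct, counts)`` where ``counts[i, j]`` is the number
    of runs protecting cell (i, j) — the raster behind overlap maps.
    """
    if len(solutions) == 0:
        raise InstanceError("run_overlap requires at least one solution")
    arrays = [_as_x(s) for s in solutions]
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise InstanceError("solutions have inconsistent shapes")
    counts = np.sum([a.astype(np.int64) for a in arrays], axis=0)
    everywhere = int((counts == len(arrays)).sum())
    return 100.0 * everywhere / q, counts


def landuse_stats(sol, landuse: np.ndarray,
                  categories: Sequence | None = None) -> pd.DataFrame:
    """Land-use composition of a zoning against a categorical raster.

    One row per category with columns:

    * ``region_count`` / ``protected_count`` / ``unprotected_count`` —
      cells of that category overall and split by protection status
      (the two splits always sum to the regional count);
    * ``region_pct`` — the category's share of the whole region;
    * ``protected_pct`` / ``unprotected_pct`` — the category's share of
      the protected (resp. unprotected) area;
    * ``protected_within_pct`` — the protected share within the category.

    ``categories`` fixes the row order and forces zero rows for absent
    categories; by default the sorted distinct values of the map are used.
    """
    x = _as_x(sol)
    landuse = np.asarray(landuse)
    if x.shape != landuse.shape:
        raise InstanceError(
            f"solution shape {x.shape} != land-use shape {landuse.shape}")
    if categories is None:
        categories = np.unique(landuse)
    rows = []
    n_total = landuse.size
    n_prot = int(x.sum())
    n_unprot = n_total - n_prot
    for cat in categories:
        in_cat = landuse == cat
        region = int(in_cat.sum())
        prot = int((in_cat & x).sum())
        unprot = region - prot
        rows.append({
            "category": cat,
            "region_count": region,
            "protected_count": prot,
            "unprotected_count": unprot,
            "region_pct": 100.0 * region / n_total,
            "protected_pct": 100.0 * prot / n_prot if n_prot else 0.0,
            "unprotected_pct": 100.0 * unprot / n_unprot if n_unprot else 0.0,
            "protected_within_pct": 100.0 * prot / region if region else 0.0,
        })
    return pd.DataFrame(rows)
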