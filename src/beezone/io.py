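"""Raster input/output, layer combination and run configuration.

Grid convention: row 0 is the top (northernmost) row, indices are
0-based (row, col) in row-major order.  Supported formats, chosen by
file suffix:

* ``.asc`` / ``.agr`` / ``.txt`` — ESRI ASCII grid (the portable text
  format; full header round trip).
* ``.tif`` / ``.tiff`` — plain TIFF via :mod:`tifffile`; cell size,
  origin and nodata are not stored in the file, so defaults apply on
  read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, InstanceError, RasterIOError
from .iabc import IABCConfig
from .model import CompactnessSpec, Solution, SuitabilityGrid, Weights

__all__ = [
    "RasterMeta",
    "read_raster",
    "write_raster",
    "write_solution",
    "load_grid",
    "weighted_linear_summation",
    "RunConfig",
]

log = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class RasterMeta:
    """Geometry and nodata convention of a raster layer."""

    n_rows: int
    n_cols: int
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata: float = DEFAULT_NODATA

    def compatible(self, other: "RasterMeta", tol: float = 1e-9) -> bool:
        return (self.n_rows == other.n_rows and self.n_cols == other.n_cols
                and abs(self.xllcorner - other.xllcorner) <= tol
                and abs(self.yllcorner - other.yllcorner) <= tol
                and abs(self.cellsize - other.cellsize) <= tol)


_ASCII_SUFFIXES = {".asc", ".agr", ".txt"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _read_ascii(path: Path) -> tuple[np.ndarray, RasterMeta]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise RasterIOError(f"{path}: truncated ESRI ASCII grid")
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        try:
            n_cols = int(header["ncols"])
            n_rows = int(header["nrows"])
        except KeyError as exc:
            raise RasterIOError(f"{path}: missing header field {exc}") from exc
        values = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise RasterIOError(
            f"{path}: data shape {values.shape} does not match header "
            f"({n_rows}, {n_cols})")
    meta = RasterMeta(
        n_rows=n_rows, n_cols=n_cols,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
    return values, meta


def _write_ascii(values: np.ndarray, meta: RasterMeta, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {meta.n_cols}\n")
        fh.write(f"nrows {meta.n_rows}\n")
        fh.write(f"xllcorner {meta.xllcorner!r}\n")
        fh.write(f"yllcorner {meta.yllcorner!r}\n")
        fh.write(f"cellsize {meta.cellsize!r}\n")
        fh.write(f"nodata_value {meta.nodata!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_raster(path) -> tuple[np.ndarray, RasterMeta]:
    """Read a raster layer; returns ``(values, meta)`` with values as-is
    (nodata cells keep the nodata code)."""
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        return _read_ascii(path)
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        try:
            values = np.asarray(tifffile.imread(path), dtype=np.float64)
        except Exception as exc:  # pragma: no cover - library-specific
            raise RasterIOError(f"cannot read TIFF {path}: {exc}") from exc
        if values.ndim != 2:
            raise RasterIOError(f"{path}: expected a single-band raster")
        return values, RasterMeta(n_rows=values.shape[0], n_cols=values.shape[1])
    raise RasterIOError(f"unsupported raster format: {path}")


def write_raster(values: np.ndarray, meta: RasterMeta, path) -> None:
    """Write a raster layer in the format implied by the file suffix."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (meta.n_rows, meta.n_cols):
        raise InstanceError(
            f"values shape {values.shape} does not match meta "
            f"({meta.n_rows}, {meta.n_cols})")
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        _write_ascii(values, meta, path)
        return
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, values)
        return
    raise RasterIOError(f"unsupported raster format: {path}")


def write_solution(sol, meta: RasterMeta, path,
                   nodata_mask: np.ndarray | None = None) -> None:
    """Write a binary protection raster (1 = protected, 0 = not); cells in
    ``nodata_mask`` are written with the nodata code."""
    x = sol.x if isinstance(sol, Solution) else np.asarray(sol).astype(bool)
    values = x.astype(np.float64)
    if nodata_mask is not None:
        values = np.where(np.asarray(nodata_mask, dtype=bool), meta.nodata, values)
    write_raster(values, meta, path)


def load_grid(eco_path, dev_path, mask_path=None) -> tuple[SuitabilityGrid, RasterMeta]:
    """Assemble a :class:`SuitabilityGrid` from raster files.

    Layers must share shape and geometry.  Nodata cells (in any layer)
    become non-configurable and their values are zeroed; all remaining
    values must lie in [0, 1] — out-of-range data is a hard error rather
    than being clamped.
    """
    eco, meta = read_raster(eco_path)
    dev, meta_dev = read_raster(dev_path)
    if not meta.compatible(meta_dev):
        raise RasterIOError(
            f"geometry mismatch between {eco_path} and {dev_path}")
    nodata = (eco == meta.nodata) | (dev == meta_dev.nodata)
    configurable = ~nodata
    if mask_path is not None:
        mask_vals, meta_mask = read_raster(mask_path)
        if not meta.compatible(meta_mask):
            raise RasterIOError(
                f"geometry mismatch between {eco_path} and {mask_path}")
        configurable &= (mask_vals != meta_mask.nodata) & (mask_vals > 0.5)
    eco = np.where(nodata, 0.0, eco)
    dev = np.where(nodata, 0.0, dev)
    grid = SuitabilityGrid(eco=eco, dev=dev, configurable=configurable)
    return grid, meta


def weighted_linear_summation(layers, weights) -> np.ndarray:
    """Combine normalized factor layers into one map: per-cell Σ w_k·layer_k.

    The standard multi-criteria combination step used to build suitability
    maps from factor rasters with externally supplied (e.g. AHP) weights.
    Weights must be non-negative and sum to 1; layers must lie in [0, 1].
    """
    weights = np.asarray(weights, dtype=np.float64)
    if len(layers) != weights.size or weights.size == 0:
        raise ConfigurationError(
            f"got {len(layers)} layers but {weights.size} weights")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"weights must be non-negative and sum to 1, got {weights.tolist()}")
    out = np.zeros_like(np.asarray(layers[0], dtype=np.float64))
    for w, layer in zip(weights, layers):
        layer = np.asarray(layer, dtype=np.float64)
        if layer.shape != out.shape:
            raise InstanceError("layers have inconsistent shapes")
        if layer.min() < 0.0 or layer.max() > 1.0:
            raise InstanceError("layers must be normalized to [0, 1]")
        out += w * layer
    return out


@dataclass
class RunConfig:
    """Declarative description of one optimization run (YAML-loadable).

    Either ``synthetic`` is true (the built-in validation surface is
    generated) or ``eco``/``dev`` (and optionally ``mask``) point to
    raster files.
    """

    q: int
    eco: str | None = None
    dev: str | None = None
    mask: str | None = None
    synthetic: bool = False
    weights: tuple[float, float, float] = (0.34, 0.33, 0.33)
    window: int = 3
    sn: int = 12
    limit: int = 150
    mcn: int = 1000
    init_pseudo_prob: float = 0.5
    init_best_fraction: float = 0.5
    swap_count_range: tuple[int, int] = (20, 40)
    p_replace_rect: float = 0.5
    p_alter_best: float = 0.5
    seed: int = 0
    out: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "q" not in raw:
            raise ConfigurationError(f"{path}: missing required key 'q'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
        if "weights" in raw:
            raw["weights"] = tuple(float(v) for v in raw["weights"])
        if "swap_count_range" in raw:
            raw["swap_count_range"] = tuple(int(v) for v in raw["swap_count_range"])
        cfg = cls(**raw)
        if not cfg.synthetic and (cfg.eco is None or cfg.dev is None):
            raise ConfigurationError(
                f"{path}: provide 'eco' and 'dev' paths or set 'synthetic: true'")
        return cfg

    def to_iabc_config(self) -> IABCConfig:
        w1, w2, w3 = self.weights
        return IABCConfig(
            q=self.q,
            weights=Weights(w1, w2, w3),
            compactness=CompactnessSpec(self.window),
            sn=self.sn,
            limit=self.limit,
            mcn=self.mcn,
            init_pseudo_prob=self.init_pseudo_prob,
            init_best_fraction=self.init_best_fraction,
            swap_count_range=self.swap_count_range,
            p_replace_rect=self.p_replace_rect,
            p_alter_best=self.p_alter_best,
            rng_seed=self.seed,
        )

    def config_hash(self) -> str:
        payload = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return hashlib.sha256(
            json.dumps(payload, default=str, sort_keys=True).encode()).hexdigest()[:12]
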