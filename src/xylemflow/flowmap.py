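"""Rasters of per-pixel mass flow and the windowed residual objective.

A FlowMap holds a 2-D raster of mass flow rate (µg s⁻¹ per pixel) on a square
grid, together with the pixel size, an optional rigid in-plane registration
offset, and an optional domain mask.  Model flow solutions are compared to an
observed map by summing each vessel's top-slice flow into the pixel containing
its centroid, forming per-pixel residuals, averaging them over a 5×5 pixel
neighbourhood (to tolerate small tissue deformation between imaging
modalities) and summing the squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# mask bit flags; 0 == excluded
MASK_INNER = 1
MASK_OUTER = 2
MASK_DORSAL_VENTRAL = 4
MASK_LATERAL = 8
MASK_LABELS = {
    "inner": MASK_INNER,
    "outer": MASK_OUTER,
    "dorsal_ventral": MASK_DORSAL_VENTRAL,
    "lateral": MASK_LATERAL,
}


@dataclass
class PixelGrid:
    """Square pixel grid in physical µm coordinates.

    ``origin_um`` is the physical (x, y) of the outer corner of pixel (0, 0);
    pixels are indexed row-major, row i along +y and column j along +x.
    ``offset_um`` is a rigid registration offset added to vessel coordinates
    before binning.
    """
    shape: tuple[int, int]
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_um}")

    def pixel_of(self, x_um: float, y_um: float) -> tuple[int, int] | None:
        """(row, col) containing the physical point, or None if outside."""
        j = int(np.floor((x_um + self.offset_um[0] - self.origin_um[0])
                         / self.pixel_size_um))
        i = int(np.floor((y_um + self.offset_um[1] - self.origin_um[1])
                         / self.pixel_size_um))
        if 0 <= i < self.shape[0] and 0 <= j < self.shape[1]:
            return i, j
        return None


@dataclass
class FlowMap:
    values: np.ndarray
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    offset_um: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("flow map raster must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_um}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match raster shape")
        if not np.all(np.isfinite(self.values[self.include])):
            raise ValueError("flow map contains non-finite values in unmasked pixels")

    @property
    def include(self) -> np.ndarray:
        """Boolean raster of pixels that participate in fitting."""
        if self.mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.mask != 0

    def domain(self, label: str) -> np.ndarray:
        """Boolean raster for a named domain (e.g. 'inner')."""
        if self.mask is None:
            raise ValueError("flow map has no domain mask")
        return (self.mask & MASK_LABELS[label]) != 0

    @property
    def grid(self) -> PixelGrid:
        return PixelGrid(self.values.shape, self.pixel_size_um,
                         self.origin_um, self.offset_um)

    def with_values(self, values: np.ndarray) -> "FlowMap":
        return replace(self, values=np.asarray(values, dtype=float))

    @property
    def total(self) -> float:
        return float(self.values[self.include].sum())


def downsample_to_pixels(solution, grid: PixelGrid,
                         assignment: str = "centroid",
                         subsamples: int = 4) -> np.ndarray:
    """Bin per-vessel top-slice flows onto a pixel grid.

    Each vessel contributes its top-slice flow to the pixel containing the
    (x, y) of its top node (``assignment='centroid'``), or spread over the
    pixels covered by its lumen circle in proportion to overlap area,
    approximated on a ``subsamples``² grid (``assignment='area'``).  Vessels
    whose centroid falls outside the grid are dropped with a warning.
    """
    if assignment not in ("centroid", "area"):
        raise ValueError(f"unknown assignment {assignment!r}")
    net = solution.network
    raster = np.zeros(grid.shape)
    dropped = []
    for v, q in solution.vessel_top_flow.items():
        node = net.node(net.top_node_of_vessel(v))
        if assignment == "centroid":
            px = grid.pixel_of(node.x, node.y)
            if px is None:
                dropped.append(v)
                continue
            raster[px] += q
        else:
            r = net.vessel_lumens(v)[-1].radius_um
            ticks = (np.arange(subsamples) + 0.5) / subsamples * 2.0 - 1.0
            xx, yy = np.meshgrid(ticks, ticks)
            inside = xx ** 2 + yy ** 2 <= 1.0
            pts = [(node.x + r * x, node.y + r * y)
                   for x, y, m in zip(xx.ravel(), yy.ravel(), inside.ravel()) if m]
            hit = [grid.pixel_of(x, y) for x, y in pts]
            hit = [h for h in hit if h is not None]
            if not hit:
                dropped.append(v)
                continue
            w = q / len(hit)
            for h in hit:
                raster[h] += w
    if dropped:
        logger.warning("%d vessels fell outside the pixel grid and were dropped: %s",
                       len(dropped), dropped[:10])
    return raster


def smooth_mask_aware(arr: np.ndarray, include: np.ndarray,
                      size: int = 5) -> np.ndarray:
    """Moving average over a size×size window, normalised by the number of
    unmasked in-window pixels; masked pixels contribute nothing."""
    inc = include.astype(float)
    num = ndimage.uniform_filter(np.where(include, arr, 0.0), size=size,
                                 mode="constant", cval=0.0)
    den = ndimage.uniform_filter(inc, size=size, mode="constant", cval=0.0)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def residual_objective(model: np.ndarray, observed: np.ndarray,
                       include: np.ndarray | None = None,
                       size: int = 5) -> tuple[float, np.ndarray]:
    """Windowed sum-of-squares residual objective.

    residual = model − observed per unmasked pixel, averaged over a size×size
    neighbourhood (mask-aware at borders), then summed as squares over the
    unmasked pixels.  Zero iff model equals observation on unmasked pixels.
    """
    model = np.asarray(model, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if model.shape != observed.shape:
        raise ValueError(f"raster shapes differ: {model.shape} vs {observed.shape}")
    if include is None:
        include = np.ones(model.shape, dtype=bool)
    elif include.shape != model.shape:
        raise ValueError("include mask shape does not match rasters")
    smoothed = smooth_mask_aware(model - observed, include, size=size)
    objective = float(np.sum(smoothed[include] ** 2))
    return objective, smoothed
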