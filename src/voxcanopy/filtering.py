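"""Ghost-point filtering on organized scan grids.

A return is kept when enough of its kernel-box neighbors lie at a similar
range: with defaults, at least 75% of the valid neighbors within a 5×5
cell box must differ in range by strictly less than 0.02 m.  The
comparison metric is the range difference (the scan's native 2-D
re-projection), not 3-D point distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .scan import ScanGrid

log = logging.getLogger(__name__)

__all__ = ["FilterParameters", "filter_ghost_points", "apply_filter"]


@dataclass
class FilterParameters:
    """Neighborhood criteria for the mixed-pixel filter.

    ``distance_threshold``: strict upper bound on |Δrange| to a neighbor (m).
    ``allocation_fraction``: minimum fraction of valid neighbors within the
    threshold.  ``kernel_half_width`` of 2 gives the default 5×5 box.
    """

    distance_threshold: float = 0.02
    allocation_fraction: float = 0.75
    kernel_half_width: int = 2

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be > 0")
        if not (0.0 < self.allocation_fraction <= 1.0):
            raise ValueError("allocation_fraction must be in (0, 1]")
        if self.kernel_half_width < 1:
            raise ValueError("kernel must include at least the 8-neighborhood")


def filter_ghost_points(grid: ScanGrid, params: FilterParameters | None = None) -> np.ndarray:
    """Keep-mask per cell; True = return retained.

    Cells without a return are False.  A valid cell is kept iff
    ``(# valid neighbors with |Δr| < threshold) / (# valid neighbors) >=
    allocation_fraction``; the center is excluded from its own count and a
    cell whose neighborhood holds no valid neighbor is removed (no
    supporting surface evidence).  The kernel is truncated at grid edges.
    """
    params = params or FilterParameters()
    h = params.kernel_half_width
    r = grid.range
    rows, cols = r.shape
    if rows < 2 * h + 1 or cols < 2 * h + 1:
        raise ValueError(
            f"kernel {2*h+1}x{2*h+1} larger than grid {rows}x{cols}"
        )
    pad = np.pad(r, h, constant_values=np.nan)
    win = sliding_window_view(pad, (2 * h + 1, 2 * h + 1))  # (rows, cols, k, k)
    diff = np.abs(win - r[..., None, None])
    valid = np.isfinite(win)
    valid[..., h, h] = False  # center excluded from its own neighborhood
    with np.errstate(invalid="ignore"):
        within = valid & (diff < params.distance_threshold)
    n_valid = valid.sum(axis=(2, 3))
    n_within = within.sum(axis=(2, 3))
    has_return = np.isfinite(r)
    no_evidence = has_return & (n_valid == 0)
    if no_evidence.any():
        log.info("%d returns removed with all-empty neighborhoods", int(no_evidence.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_valid > 0, n_within / np.maximum(n_valid, 1), 0.0)
    return has_return & (frac >= params.allocation_fraction)


def apply_filter(grid: ScanGrid, keep: np.ndarray) -> ScanGrid:
    """New ScanGrid with removed returns blanked to NaN."""
    rng = np.where(keep, grid.range, np.nan)
    pts = np.where(keep[..., None], grid.points, np.nan)
    labels = None
    if grid.labels is not None:
        labels = np.where(keep, grid.labels, -1)
    return ScanGrid(
        azimuth_deg=grid.azimuth_deg,
        elevation_deg=grid.elevation_deg,
        range=rng,
        points=pts,
        scanner_position=grid.scanner_position,
        labels=labels,
    )
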