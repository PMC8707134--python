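"""Split-plot trial geometry: blocks, plots, measurement spots.

The default layout emulates a protected-crop trial on parallel beds: each
block is one 1.3 m wide bed, split longitudinally into two halves (one per
main-plot factor level, e.g. compost YES/NO) separated by a configurable gap
(the two-tunnel split), each half carrying one 3.0 x 1.3 m plot per sub-plot
factor level (the inducer treatments).  Twelve measurement spots per plot sit
on a grid at 0.5 m spacing.  With the defaults this gives
4 blocks x 2 halves x 5 plots = 40 plots and 480 spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrialDesign", "generate_design", "MAIN_LEVELS", "SUB_LEVELS"]

MAIN_LEVELS = ("NO", "YES")
SUB_LEVELS = ("TRI", "LAM", "CER", "CHE", "CTR")

#: alley between adjacent beds, metres
ALLEY = 0.5


@dataclass(frozen=True)
class TrialDesign:
    """A realized split-plot layout.

    Attributes
    ----------
    plots:
        One row per plot: ``plot, block, half, main, sub, x0, y0, width, depth``.
    spots:
        One row per measurement spot: ``spot, plot, block, half, main, sub, x, y``.
    main_levels, sub_levels:
        Factor level orderings (the last level is the reference level in the
        fixed-effect parameterization downstream).
    """

    plots: pd.DataFrame
    spots: pd.DataFrame
    main_levels: tuple
    sub_levels: tuple

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def locations(self) -> np.ndarray:
        """Spot coordinates as an (n, 2) array, in spot order."""
        return self.spots[["x", "y"]].to_numpy(dtype=float)


def _spot_grid(plot_w: float, plot_d: float, spots_per_plot: int, spacing: float):
    """Choose an nx x ny grid of spots that fits the plot rectangle.

    Among factor pairs nx * ny = spots_per_plot, the widest grid that fits
    (largest nx along the plot width) is used; for 12 spots in a 3.0 x 1.3 m
    plot this is 6 x 2.  The grid is centered in the rectangle.
    """
    best = None
    for ny in range(1, spots_per_plot + 1):
        if spots_per_plot % ny:
            continue
        nx = spots_per_plot // ny
        if (nx - 1) * spacing <= plot_w and (ny - 1) * spacing <= plot_d:
            if best is None or nx > best[0]:
                best = (nx, ny)
    if best is None:
        raise ValueError(
            f"no {spots_per_plot}-spot grid at {spacing} m spacing fits a "
            f"{plot_w} x {plot_d} m plot"
        )
    nx, ny = best
    xs = (plot_w - (nx - 1) * spacing) / 2 + spacing * np.arange(nx)
    ys = (plot_d - (ny - 1) * spacing) / 2 + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def generate_design(
    n_blocks: int = 4,
    plot_w: float = 3.0,
    plot_d: float = 1.3,
    spots_per_plot: int = 12,
    spacing: float = 0.5,
    tunnel_gap: float = 2.0,
    main_levels: tuple = MAIN_LEVELS,
    sub_levels: tuple = SUB_LEVELS,
    seed: int = 1,
) -> TrialDesign:
    """Generate a randomized two-way split-plot design.

    Each block is a bed running along x at ``y = block * (plot_d + alley)``.
    The bed is split into two halves separated by ``tunnel_gap`` m; the main
    factor levels are randomly assigned to the halves per block, and within
    each half the sub-plot levels are randomly permuted over contiguous plots.
    The same ``seed`` always reproduces the identical design.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = _spot_grid(plot_w, plot_d, spots_per_plot, spacing)
    n_halves = len(main_levels)
    n_sub = len(sub_levels)

    plot_rows, spot_rows = [], []
    plot_id = 0
    spot_id = 0
    for b in range(n_blocks):
        y0 = b * (plot_d + ALLEY)
        main_order = rng.permutation(n_halves)
        for half in range(n_halves):
            main = main_levels[main_order[half]]
            sub_order = rng.permutation(n_sub)
            x_half = half * (n_sub * plot_w + tunnel_gap)
            for j in range(n_sub):
                sub = sub_levels[sub_order[j]]
                x0 = x_half + j * plot_w
                plot_rows.append(
                    dict(plot=plot_id, block=b, half=half, main=main, sub=sub,
                         x0=x0, y0=y0, width=plot_w, depth=plot_d)
                )
                for dx, dy in offsets:
                    spot_rows.append(
                        dict(spot=spot_id, plot=plot_id, block=b, half=half,
                             main=main, sub=sub, x=x0 + dx, y=y0 + dy)
                    )
                    spot_id += 1
                plot_id += 1

    return TrialDesign(
        plots=pd.DataFrame(plot_rows),
        spots=pd.DataFrame(spot_rows),
        main_levels=tuple(main_levels),
        sub_levels=tuple(sub_levels),
    )
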