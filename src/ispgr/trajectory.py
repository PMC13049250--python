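"""Pseudo-spiral Cartesian phase-encode ordering with golden-angle rotation.

Each shot acquires one spiral arm on the Cartesian (ky, kz) phase-encode
grid.  The arm is the curve r = -x^2 + 2x, phi = 2*pi*x + rotation for
x in [0, 1], sampled at uniformly spaced x, so it starts exactly at the
grid center (r(0) = 0) and reaches the grid edge (r(1) = 1).  Radius is
scaled anisotropically so the unit circle touches both extents of the
non-square grid, then each polar sample is rounded to the nearest integer
grid index and clipped to bounds.  Successive arms are rotated by the
golden angle (137 deg), giving dense central coverage with undersampled
periphery.

Grid convention: 0-based integer indices with DC at ``floor(n/2)``.
Duplicate indices inside an arm (common near the center after rounding) are
kept: the sequence plays all k readouts regardless, so repeats are repeated
acquisitions, not waste.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryPlan",
    "spiral_arm",
    "generate_trajectory",
    "sampling_report",
    "region_density",
]

GOLDEN_ANGLE_DEG = 137.0
DEFAULT_GRID = (178, 30)
DEFAULT_POINTS_PER_ARM = 30


@dataclass(frozen=True)
class TrajectoryPlan:
    """A full phase-encode ordering: one center-out arm per shot."""

    grid: tuple[int, int]
    points_per_arm: int
    n_shots: int
    golden_angle: float
    arms: tuple[np.ndarray, ...]  # each (points_per_arm, 2) int array of (ky, kz)

    def __post_init__(self) -> None:
        ny, nz = self.grid
        for arm in self.arms:
            if arm.shape != (self.points_per_arm, 2):
                raise ValueError("each arm must have exactly points_per_arm entries")
            if (arm[:, 0] < 0).any() or (arm[:, 0] >= ny).any() \
                    or (arm[:, 1] < 0).any() or (arm[:, 1] >= nz).any():
                raise ValueError("arm index outside grid bounds")

    @property
    def center(self) -> tuple[int, int]:
        return (self.grid[0] // 2, self.grid[1] // 2)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, arm in enumerate(self.arms):
            for order, (ky, kz) in enumerate(arm):
                rows.append((s, order, int(ky), int(kz)))
        return pd.DataFrame(rows, columns=["shot", "order", "ky", "kz"])

    def sample_mask(self) -> np.ndarray:
        """Boolean (ny, nz) mask of grid points sampled at least once."""
        mask = np.zeros(self.grid, dtype=bool)
        for arm in self.arms:
            mask[arm[:, 0], arm[:, 1]] = True
        return mask

    def visit_counts(self) -> np.ndarray:
        counts = np.zeros(self.grid, dtype=int)
        for arm in self.arms:
            np.add.at(counts, (arm[:, 0], arm[:, 1]), 1)
        return counts


def spiral_arm(
    rotation: float,
    grid: tuple[int, int] = DEFAULT_GRID,
    points_per_arm: int = DEFAULT_POINTS_PER_ARM,
) -> np.ndarray:
    """One spiral arm as ordered (ky, kz) grid indices, center-out.

    Parameters
    ----------
    rotation : float
        Rotation of the arm, degrees.
    grid : (int, int)
        Phase-encode matrix size (n_ky, n_kz).
    points_per_arm : int
        Number of sampled points along the arm.
    """
    ny, nz = grid
    if ny < 1 or nz < 1 or points_per_arm < 1:
        raise ValueError("grid dimensions and points_per_arm must be >= 1")
    x = np.linspace(0.0, 1.0, points_per_arm)
    r = -x * x + 2.0 * x
    phi = 2.0 * np.pi * x + np.deg2rad(rotation)
    cy, cz = ny // 2, nz // 2
    ky = cy + np.rint(r * np.cos(phi) * ny / 2.0).astype(int)
    kz = cz + np.rint(r * np.sin(phi) * nz / 2.0).astype(int)
    np.clip(ky, 0, ny - 1, out=ky)
    np.clip(kz, 0, nz - 1, out=kz)
    return np.column_stack([ky, kz])


def generate_trajectory(
    n_shots: int,
    grid: tuple[int, int] = DEFAULT_GRID,
    points_per_arm: int = DEFAULT_POINTS_PER_ARM,
    golden_angle: float = GOLDEN_ANGLE_DEG,
) -> TrajectoryPlan:
    """Deterministic plan of ``n_shots`` arms; arm ``i`` is rotated ``i * golden_angle``."""
    if n_shots < 1:
        raise ValueError(f"n_shots must be >= 1, got {n_shots}")
    arms = tuple(
        spiral_arm(i * golden_angle, grid, points_per_arm) for i in range(n_shots)
    )
    return TrajectoryPlan(
        grid=tuple(grid), points_per_arm=points_per_arm,
        n_shots=n_shots, golden_angle=golden_angle, arms=arms,
    )


def _normalized_radius(grid: tuple[int, int]) -> np.ndarray:
    """Elliptically normalized radius of every grid point (1.0 at the edge midpoints)."""
    ny, nz = grid
    cy, cz = ny // 2, nz // 2
    iy = (np.arange(ny) - cy) / (ny / 2.0)
    iz = (np.arange(nz) - cz) / (nz / 2.0)
    return np.sqrt(iy[:, None] ** 2 + iz[None, :] ** 2)


def sampling_report(plan: TrajectoryPlan, n_bins: int = 10) -> pd.DataFrame:
    """Coverage per normalized-radius bin.

    Columns: ``r_lo``/``r_hi`` (bin edges of the elliptical normalized
    radius), ``n_grid`` (grid points in the bin), ``fraction_sampled``
    (fraction sampled at least once) and ``mean_visits`` (mean acquisition
    count over the bin's grid points).
    """
    rho = _normalized_radius(plan.grid)
    mask = plan.sample_mask()
    counts = plan.visit_counts()
    edges = np.linspace(0.0, float(rho.max()) + 1e-9, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (rho >= lo) & (rho < hi)
        n_grid = int(sel.sum())
        if n_grid == 0:
            frac, visits = np.nan, np.nan
        else:
            frac = float(mask[sel].mean())
            visits = float(counts[sel].mean())
        rows.append((lo, hi, n_grid, frac, visits))
    return pd.DataFrame(
        rows, columns=["r_lo", "r_hi", "n_grid", "fraction_sampled", "mean_visits"]
    )


def region_density(plan: TrajectoryPlan, r_lo: float, r_hi: float = np.inf) -> float:
    """Fraction of grid points with normalized radius in [r_lo, r_hi] sampled
    at least once.

    Pass ``r_hi = inf`` (default) for the full grid periphery beyond
    ``r_lo``: on a rectangular grid the corners (radius up to ~1.41) belong
    to peripheral k-space even though the unit-radius spiral never reaches
    them.  Note the arm parametrization flattens (dr/dx -> 0) at the edge,
    so the thin ring just inside radius 1 is itself relatively densely
    sampled; peripheral *under*-sampling is a statement about the periphery
    as a whole and about visit density, not about that ring.
    """
    rho = _normalized_radius(plan.grid)
    sel = (rho >= r_lo) & (rho <= r_hi)
    if not sel.any():
        raise ValueError("empty radius region")
    return float(plan.sample_mask()[sel].mean())
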