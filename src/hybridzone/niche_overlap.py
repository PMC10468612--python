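"""Ordination-based climatic niche overlap (PCA-env, Schoener's D).

Workflow: drop inter-correlated variables (|Pearson r| below a threshold
survives), PCA of the standardized environmental background, kernel
occupancy grids of each species' occurrences on the first two axes
corrected for background availability, Schoener's D, similarity permutation
tests by random translation of the occupancy density, and a projection of
the shared suitable niche back into geography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_model_io import OccurrenceSet, RasterStack


def select_variables(stack: RasterStack, r_threshold: float = 0.7) -> list[str]:
    """Greedy decorrelation of the layer set.

    While any pair has |Pearson r| >= threshold over the valid background
    cells, drop the member of the worst pair with the larger mean absolute
    correlation against all remaining layers (ties: the later layer in
    stack order). Deterministic.
    """
    table = stack.table()[stack.names]
    if table.empty:
        raise ValueError("no valid cells shared across layers")
    keep = list(stack.names)
    while len(keep) > 1:
        corr = table[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < r_threshold:
            break
        mean_abs = corr.sum(axis=0) / (len(keep) - 1)
        drop = j if mean_abs[j] >= mean_abs[i] else i
        keep.pop(max(i, j) if mean_abs[i] == mean_abs[j] else drop)
    return keep


@dataclass
class EnvPca:
    variables: list[str]
    mean: np.ndarray
    scale: np.ndarray
    pca: PCA

    @property
    def variance_explained(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        z = (table[self.variables].to_numpy(float) - self.mean) / self.scale
        return self.pca.transform(z)[:, :2]


def pca_env(stack: RasterStack, variables: list[str] | None = None) -> tuple[EnvPca, np.ndarray]:
    """PCA of the standardized background cloud; returns the fitted
    ordination and the background scores on the first two axes."""
    variables = variables or list(stack.names)
    table = stack.table()
    if len(table) < 3:
        raise ValueError("need at least 3 background cells")
    X = table[variables].to_numpy(float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    for name, s in zip(variables, scale):
        if s == 0:
            raise ValueError(f"variable {name!r} is constant over the background")
    Z = (X - mean) / scale
    pca = PCA(n_components=min(len(variables), Z.shape[0])).fit(Z)
    env = EnvPca(variables, mean, scale, pca)
    return env, pca.transform(Z)[:, :2]


def env_scores_of_occurrences(
    stack: RasterStack, env: EnvPca, occurrences: OccurrenceSet
) -> np.ndarray:
    """Project occurrence records into the ordination via their nearest
    raster cell's environmental values. Records on nodata cells are dropped."""
    rows = np.abs(stack.lat[:, None] - occurrences.latitudes[None, :]).argmin(axis=0)
    cols = np.abs(stack.lon[:, None] - occurrences.longitudes[None, :]).argmin(axis=0)
    ok = stack.valid_mask[rows, cols]
    if not ok.any():
        raise ValueError("all occurrences fall on nodata cells")
    data = {
        name: stack.values[k][rows[ok], cols[ok]]
        for k, name in enumerate(stack.names)
    }
    return env.transform(pd.DataFrame(data))


@dataclass
class NicheGrid:
    """Background-corrected kernel occupancy on the ordination plane.

    ``z`` sums to 1; ``extent`` = (x0, x1, y0, y1) of the background's
    PC1-PC2 range shared by every grid in a comparison.
    """

    species: str
    z: np.ndarray
    background: np.ndarray
    extent: tuple[float, float, float, float]

    @property
    def R(self) -> int:
        return self.z.shape[0]


def _axis_grid(extent, R):
    x0, x1, y0, y1 = extent
    return (np.linspace(x0, x1, R), np.linspace(y0, y1, R))


def _kde2(points: np.ndarray, xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    """Product-Gaussian KDE with per-axis Silverman bandwidth
    h_j = sigma_j n^(-1/6)."""
    n = points.shape[0]
    h = points.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)
    h = np.where(h > 0, h, 1e-3)
    dx = (xg[None, :] - points[:, 0, None]) / h[0]
    dy = (yg[None, :] - points[:, 1, None]) / h[1]
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    # outer product per point, summed: (R_y, R_x)
    return ky.T @ kx / (n * 2 * np.pi * h[0] * h[1])


def occupancy_grid(
    occurrence_scores: np.ndarray,
    background_scores: np.ndarray,
    species: str = "",
    R: int = 100,
    background_floor_percentile: float = 1.0,
) -> NicheGrid:
    """Kernel occupancy of a species in environment space.

    Occurrence density (Gaussian KDE) on the R x R grid spanning the
    background's PC1-PC2 range, divided by background availability measured
    as the per-cell count of background cells (a smooth background density
    estimate spans many orders of magnitude near the cloud edge and makes
    the ratio explode; counts bound the divisor from below). The divisor is
    floored at the given percentile of the positive counts, cells with no
    background are zeroed, and the grid is renormalized to sum 1.
    """
    if occurrence_scores.shape[0] < 5:
        raise ValueError("need at least 5 occurrences")
    bx, by = background_scores[:, 0], background_scores[:, 1]
    extent = (float(bx.min()), float(bx.max()), float(by.min()), float(by.max()))
    ox, oy = occurrence_scores[:, 0], occurrence_scores[:, 1]
    inside = (ox >= extent[0]) & (ox <= extent[1]) & (oy >= extent[2]) & (oy <= extent[3])
    if not inside.any():
        raise ValueError("all occurrences outside the background extent")
    xg, yg = _axis_grid(extent, R)
    occ = _kde2(occurrence_scores[inside], xg, yg)
    counts, _, _ = np.histogram2d(
        by, bx, bins=[np.linspace(extent[2], extent[3], R + 1),
                      np.linspace(extent[0], extent[1], R + 1)],
    )
    present = counts > 0
    floor = np.percentile(counts[present], background_floor_percentile)
    z = np.where(present, occ / np.maximum(counts, floor), 0.0)
    total = z.sum()
    if total == 0:
        raise ValueError("empty occupancy after background correction")
    return NicheGrid(species, z / total, counts, extent)


def schoeners_d(z1: NicheGrid, z2: NicheGrid) -> float:
    """D = 1 - 0.5 sum |z1 - z2|; 1 for identical niches, 0 for disjoint."""
    if z1.z.shape != z2.z.shape or not np.allclose(z1.extent, z2.extent):
        raise ValueError("niche grids are not aligned")
    return float(1.0 - 0.5 * np.abs(z1.z - z2.z).sum())


def similarity_test(
    grid_a: NicheGrid,
    grid_b: NicheGrid,
    n_reps: int = 100,
    seed: int = 0,
    direction: str = "similar",
) -> float:
    """Niche similarity permutation test (one direction).

    The null relocates species B's corrected occupancy by a random toroidal
    translation within B's background mask, and recomputes D against A.
    ``direction='similar'`` returns P(D_null >= D_obs); ``'dissimilar'``
    P(D_null <= D_obs); both with the add-one permutation correction.
    """
    if n_reps < 99:
        raise ValueError("need at least 99 repetitions")
    if direction not in ("similar", "dissimilar"):
        raise ValueError("direction must be 'similar' or 'dissimilar'")
    d_obs = schoeners_d(grid_a, grid_b)
    rng = np.random.default_rng(seed)
    R = grid_b.R
    mask = grid_b.background > 0
    if mask.sum() < 2:
        raise ValueError("background too small for relocation")
    count = 0
    for _ in range(n_reps):
        di, dj = rng.integers(0, R, size=2)
        shifted = np.roll(np.roll(grid_b.z, di, axis=0), dj, axis=1)
        shifted = np.where(mask, shifted, 0.0)
        total = shifted.sum()
        if total == 0:
            d_null = 0.0
        else:
            null_grid = NicheGrid(grid_b.species, shifted / total,
                                  grid_b.background, grid_b.extent)
            d_null = schoeners_d(grid_a, null_grid)
        if (direction == "similar" and d_null >= d_obs) or (
            direction == "dissimilar" and d_null <= d_obs
        ):
            count += 1
    return (count + 1) / (n_reps + 1)


def _occupied_mask(grid: NicheGrid, quantile: float) -> np.ndarray:
    """Cells holding the top (1 - quantile) of density mass."""
    flat = np.sort(grid.z.ravel())[::-1]
    cum = np.cumsum(flat)
    cutoff_idx = np.searchsorted(cum, 1.0 - quantile)
    cutoff = flat[min(cutoff_idx, flat.size - 1)]
    return grid.z >= max(cutoff, np.finfo(float).tiny)


def project_shared_suitability(
    grid_a: NicheGrid,
    grid_b: NicheGrid,
    stack: RasterStack,
    env: EnvPca,
    density_quantile: float = 0.05,
) -> np.ndarray:
    """Classify each geographic cell by niche membership.

    Returns an integer raster aligned with ``stack``: 0 = neither,
    1 = A only, 2 = B only, 3 = both; -1 for nodata. A species "occupies"
    the environmental cells containing the top (1 - density_quantile) of
    its occupancy mass.
    """
    occ_a = _occupied_mask(grid_a, density_quantile)
    occ_b = _occupied_mask(grid_b, density_quantile)
    scores = env.transform(stack.table())
    xg, yg = _axis_grid(grid_a.extent, grid_a.R)
    ix = np.clip(np.searchsorted(xg, scores[:, 0]), 0, grid_a.R - 1)
    iy = np.clip(np.searchsorted(yg, scores[:, 1]), 0, grid_a.R - 1)
    in_a = occ_a[iy, ix]
    in_b = occ_b[iy, ix]
    out = np.full(stack.valid_mask.shape, -1, dtype=int)
    rr, cc = np.nonzero(stack.valid_mask)
    out[rr, cc] = in_a.astype(int) + 2 * in_b.astype(int)
    return out
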