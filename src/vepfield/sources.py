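"""Discrete source space tying a brain to its pseudospectral grids.

A *source* is anything that carries epileptor state: a regular-grid node on
either cortical hemisphere, or a subcortical point node.  Sources are ordered
``[hemisphere 0 nodes, hemisphere 1 nodes, subcortical nodes]``; all model
state vectors (x, z, x0, gains) follow this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    RegularSphericalGrid,
    SphericalBrain,
    VertexToGridMap,
    build_regular_grid,
    grid_region_labels,
    map_mesh_to_grid,
    region_average,
)

__all__ = ["SourceSpace", "build_source_space"]


@dataclass
class SourceSpace:
    """Grid-resolution source layout for one brain."""

    brain: SphericalBrain
    grid: RegularSphericalGrid  # shared layout for both hemispheres
    vertex_maps: tuple[VertexToGridMap, VertexToGridMap]
    labels: np.ndarray  # (n_sources,) region id per source
    positions_mm: np.ndarray  # (n_sources, 3)
    n_regions: int

    @property
    def n_per_hemisphere(self) -> int:
        return self.grid.n_nodes

    @property
    def n_cortical(self) -> int:
        return 2 * self.grid.n_nodes

    @property
    def n_sources(self) -> int:
        return self.n_cortical + self.brain.n_subcortical

    def hemisphere_slice(self, h: int) -> slice:
        n = self.grid.n_nodes
        return slice(h * n, (h + 1) * n)

    def region_average(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-region unweighted mean of a per-source field."""
        return region_average(values, self.labels, self.n_regions)

    def region_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_regions)

    def region_members(self, region_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == region_id)


def build_source_space(brain: SphericalBrain, grid_degree: int = 32) -> SourceSpace:
    """Map a brain onto regular grids and assemble the source layout.

    Grid-node region labels are the majority label of the mesh vertices
    mapped to each node (nearest-vertex fallback for empty nodes).
    """
    grid = build_regular_grid(grid_degree)
    maps = tuple(map_mesh_to_grid(h, grid) for h in brain.hemispheres)
    labels = [
        grid_region_labels(h, grid, m) for h, m in zip(brain.hemispheres, maps)
    ]
    labels.append(brain.subcortical_regions)
    all_labels = np.concatenate(labels)

    node_units = grid.unit_vectors()
    positions = [
        brain.hemisphere_centers_mm[h] + brain.radius_mm * node_units
        for h in range(2)
    ]
    positions.append(brain.subcortical_positions_mm)
    all_positions = np.vstack(positions)

    n_regions = brain.n_regions
    return SourceSpace(
        brain=brain,
        grid=grid,
        vertex_maps=maps,  # type: ignore[arg-type]
        labels=all_labels,
        positions_mm=all_positions,
        n_regions=n_regions,
    )
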