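"""Slab-plus-blood geometry and graded tensor-product hexahedral meshes.

The computational domain is a rectangular tissue slab 16 cm x 16 cm x 1 cm
(epicardium at z = 0, endocardium at z = 1 cm) in contact with a blood
volume extending from z = 1 to z = 26 cm over the same cross-section.  A
4 cm x 4 cm ischaemic footprint is centred at the origin, so the lateral
node spacing is graded to cluster around x, y = +/-2 cm; the z spacing is
uniform and fine across the tissue and geometrically stretched through the
blood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["Geometry", "Mesh", "build_mesh", "MESH_PRESETS"]

#: Lateral half-extent of the domain [cm].
XY_EXTENT = 8.0
#: Tissue wall thickness [cm].
WALL = 1.0
#: Bottom of the blood volume [cm].
Z_MAX = 26.0
#: Half-width of the ischaemic footprint in x and y [cm].
FOOTPRINT = 2.0


@dataclass(frozen=True)
class Geometry:
    """Fixed slab-and-blood geometry with an ischaemic footprint."""

    xy_extent: float = XY_EXTENT
    wall: float = WALL
    z_max: float = Z_MAX
    footprint: float = FOOTPRINT


def _geometric_spacings(length: float, n: int, ratio: float) -> np.ndarray:
    """n cell widths summing to `length`, in geometric progression `ratio`."""
    if abs(ratio - 1.0) < 1e-12:
        return np.full(n, length / n)
    h0 = length * (ratio - 1.0) / (ratio**n - 1.0)
    return h0 * ratio ** np.arange(n)

def _graded_half_axis(n_half: int, grading: float) -> np.ndarray:
    """Nodes on [0, 8] with spacing finest at the footprint border x = 2.

    The inner segment [0, 2] and outer segment [2, 8] each get a geometric
    spacing that refines toward x = 2; cells are split between the segments
    roughly in proportion to a mild bias toward the outer (longer) segment.
    """
    n_in = max(2, round(n_half * 0.4))
    n_out = n_half - n_in
    w_in = _geometric_spacings(FOOTPRINT, n_in, 1.0 / grading)  # refine toward x = 2
    w_out = _geometric_spacings(XY_EXTENT - FOOTPRINT, n_out, grading)
    widths = np.concatenate((w_in, w_out))
    nodes = np.concatenate(([0.0], np.cumsum(widths)))
    nodes[n_in] = FOOTPRINT  # snap the footprint border and outer edge exactly
    nodes[-1] = XY_EXTENT
    return nodes


def _lateral_axis(n_cells: int, grading: float) -> np.ndarray:
    if n_cells % 2:
        raise ValueError("lateral cell count must be even (mesh is symmetric)")
    half = _graded_half_axis(n_cells // 2, grading)
    return np.concatenate((-half[::-1][:-1], half))


def _z_axis(n_tissue: int, n_blood: int) -> np.ndarray:
    """Uniform tissue spacing on [0, 1]; geometric stretch through the blood."""
    h_tissue = WALL / n_tissue
    tissue = np.linspace(0.0, WALL, n_tissue + 1)
    depth = Z_MAX - WALL

    # find stretch ratio so that the first blood cell matches the tissue cell
    def first_cell(r: float) -> float:
        if abs(r - 1.0) < 1e-12:
            return depth / n_blood
        return depth * (r - 1.0) / (r**n_blood - 1.0)

    r = brentq(lambda r: first_cell(r) - h_tissue, 1.0 + 1e-9, 10.0)
    blood = WALL + np.cumsum(_geometric_spacings(depth, n_blood, r))
    blood[-1] = Z_MAX
    return np.concatenate((tissue, blood))


@dataclass(frozen=True)
class Mesh:
    """Tensor-product hexahedral mesh; x/y graded laterally, z layered."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    n_tissue_layers: int
    preset: str = "custom"
    geometry: Geometry = Geometry()

    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.x), len(self.y), len(self.z)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return (nx - 1) * (ny - 1) * (nz - 1)

    @property
    def iz_endo(self) -> int:
        """Index of the endocardial node plane z = wall thickness."""
        return self.n_tissue_layers

    @property
    def z_layer_mid(self) -> np.ndarray:
        return 0.5 * (self.z[:-1] + self.z[1:])

    @property
    def tissue_layers(self) -> np.ndarray:
        """Boolean mask over z cell layers: True inside the tissue."""
        return self.z_layer_mid < self.geometry.wall

    def epicardial_grid(self) -> tuple[np.ndarray, np.ndarray]:
        return self.x, self.y


# (lateral cells, tissue layers, blood layers, lateral grading ratio)
MESH_PRESETS: dict[str, tuple[int, int, int, float]] = {
    # reproduces the reference resolution: 61*61*101 nodes, 360,000 cells
    "full": (60, 50, 50, 1.13),
    "coarse": (32, 20, 12, 1.25),
    "tiny": (24, 12, 8, 1.3),
}


def build_mesh(preset: str = "coarse") -> Mesh:
    """Construct one of the named mesh presets."""
    try:
        n_xy, n_t, n_b, grading = MESH_PRESETS[preset]
    except KeyError:
        raise KeyError(f"unknown mesh preset {preset!r}; options: {list(MESH_PRESETS)}")
    axis = _lateral_axis(n_xy, grading)
    return Mesh(
        x=axis, y=axis.copy(), z=_z_axis(n_t, n_b), n_tissue_layers=n_t, preset=preset
    )
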