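"""Hexahedral mesh container, density images and legacy-VTK ASCII I/O.

The exchange format is the legacy VTK unstructured-grid ASCII file with
hexahedron cells; named node sets are encoded as an integer point-data
bitmask (``node_sets`` field, bit per set) and the tissue compartment as
integer cell data (0 = cortical, 1 = trabecular).  Per-node density fields
travel as point-data scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import TissueCompartment

__all__ = ["HexMesh", "GridDensityImage", "read_vtk", "write_vtk"]

SET_NAMES = ("shaft_end", "trochanter_surface", "head_surface")


@dataclass
class HexMesh:
    """8-node hexahedral mesh with compartment labels and named node sets.

    nodes: (n_nodes, 3) coordinates in mm.
    elements: (n_elem, 8) connectivity, VTK hexahedron ordering.
    compartment: (n_elem,) array of :class:`TissueCompartment` values.
    node_sets: name -> sorted int array; the three side-fall sets
    (shaft_end, trochanter_surface, head_surface) must be non-empty and
    pairwise disjoint for the fall simulation.
    """

    nodes: np.ndarray
    elements: np.ndarray
    compartment: np.ndarray
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.compartment = np.asarray(
            [TissueCompartment(c) for c in self.compartment], dtype=object
        )
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("elements must be (m, 8)")
        if len(self.compartment) != len(self.elements):
            raise ValueError("one compartment label per element required")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= len(self.nodes):
            raise ValueError("element connectivity indexes outside the node array")
        self.node_sets = {k: np.unique(np.asarray(v, dtype=np.int64)) for k, v in self.node_sets.items()}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]

    def validate_side_fall_sets(self) -> None:
        for name in SET_NAMES:
            if name not in self.node_sets or len(self.node_sets[name]) == 0:
                raise ValueError(f"node set '{name}' is missing or empty")
        for i, a in enumerate(SET_NAMES):
            for b in SET_NAMES[i + 1 :]:
                if np.intersect1d(self.node_sets[a], self.node_sets[b]).size:
                    raise ValueError(f"node sets '{a}' and '{b}' overlap")

    def check_jacobians(self) -> None:
        from ._hex8 import element_geometry

        _, detJ = element_geometry(self.element_coords())
        if np.any(detJ <= 0):
            e = int(np.argwhere(detJ <= 0)[0][0])
            raise ValueError(f"non-positive Jacobian in element {e}")


class GridDensityImage:
    """Rectilinear 3D density image with trilinear probing.

    values[i, j, k] sits at origin + (i, j, k) * spacing; probing outside
    the grid returns NaN (callers turn that into a named-element error).
    """

    def __init__(self, origin, spacing, values):
        from scipy.interpolate import RegularGridInterpolator

        self.origin = np.asarray(origin, dtype=float)
        self.spacing = np.asarray(spacing, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density image must be a 3D array")
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.values.shape[d])
            for d in range(3)
        ]
        self._interp = RegularGridInterpolator(
            axes, self.values, method="linear", bounds_error=False, fill_value=np.nan
        )

    def probe(self, points) -> np.ndarray:
        return self._interp(np.atleast_2d(np.asarray(points, dtype=float)))


def write_vtk(path, mesh: HexMesh, point_data: dict | None = None) -> None:
    """Write the mesh (plus optional per-node scalar fields) as legacy VTK ASCII."""
    point_data = dict(point_data or {})
    mask = np.zeros(mesh.n_nodes, dtype=np.int64)
    set_names = list(mesh.node_sets)
    for bit, name in enumerate(set_names):
        mask[mesh.node_sets[name]] |= 1 << bit
    comp = np.array(
        [0 if c is TissueCompartment.CORTICAL else 1 for c in mesh.compartment]
    )
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"femofall hex mesh; node_sets={','.join(set_names)}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        cells = np.hstack([np.full((mesh.n_elements, 1), 8), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(fh, np.full(mesh.n_elements, 12), fmt="%d")
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS compartment int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, comp, fmt="%d")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("SCALARS node_sets int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mask, fmt="%d")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (mesh.n_nodes,):
                raise ValueError(f"point data '{name}' must have one value per node")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, values, fmt="%.17g")


def read_vtk(path):
    """Read a legacy VTK ASCII hexahedral mesh written by :func:`write_vtk`.

    Returns ``(mesh, point_data)`` where ``point_data`` maps field names to
    per-node arrays (e.g. a density field).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    it = iter(range(len(lines)))
    set_names = []
    if "node_sets=" in lines[1]:
        names = lines[1].split("node_sets=")[1].strip()
        set_names = [n for n in names.split(",") if n]

    def _block(start, n, dtype):
        rows = [np.fromstring(lines[i], sep=" ") for i in range(start, start + n)]
        return np.asarray(rows, dtype=dtype)

    i = next(j for j in range(len(lines)) if lines[j].startswith("POINTS"))
    n_nodes = int(lines[i].split()[1])
    nodes = _block(i + 1, n_nodes, float)
    i = next(j for j in range(len(lines)) if lines[j].startswith("CELLS"))
    n_elem = int(lines[i].split()[1])
    cells = _block(i + 1, n_elem, np.int64)
    if np.any(cells[:, 0] != 8):
        raise ValueError("only hexahedron cells are supported")
    elements = cells[:, 1:]
    i = next(j for j in range(len(lines)) if lines[j].startswith("CELL_TYPES"))
    types = _block(i + 1, n_elem, np.int64).ravel()
    if np.any(types != 12):
        raise ValueError("only VTK_HEXAHEDRON (type 12) cells are supported")

    comp_ids = None
    mask = None
    point_data: dict[str, np.ndarray] = {}
    j = 0
    while j < len(lines):
        ln = lines[j]
        if ln.startswith("SCALARS"):
            name = ln.split()[1]
            count = n_elem if name == "compartment" else n_nodes
            data = _block(j + 2, count, float)
            if name == "compartment":
                comp_ids = data.ravel().astype(np.int64)
            elif name == "node_sets":
                mask = data.ravel().astype(np.int64)
            else:
                point_data[name] = data.ravel()
            j += 2 + count
        else:
            j += 1
    if comp_ids is None:
        raise ValueError("mesh file lacks the compartment cell data")
    compartment = [
        TissueCompartment.CORTICAL if i == 0 else TissueCompartment.TRABECULAR
        for i in comp_ids
    ]
    node_sets = {}
    if mask is not None:
        for bit, name in enumerate(set_names):
            node_sets[name] = np.flatnonzero(mask & (1 << bit))
    mesh = HexMesh(nodes=nodes, elements=elements, compartment=compartment, node_sets=node_sets)
    return mesh, point_data
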