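"""Structure, grid and mesh I/O plus physical property mapping onto surfaces.

Reads PDB structures and OpenDX scalar grids, builds a triangulated
solvent-exposed surface by marching cubes over the probe-inflated atomic
distance field, and maps three property channels (electrostatic potential,
Kyte-Doolittle hydrophobicity, hydrogen-bond capability) onto surface
triangles.

Conventions: lengths in angstrom, right-handed PDB frame; OpenDX grids are
stored x-slowest (C order over (nx, ny, nz)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    FormatError,
    MappingError,
    UnsupportedGridError,
)

# ---------------------------------------------------------------------------
# constant tables
# ---------------------------------------------------------------------------

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: van der Waals radii (angstrom) by element symbol.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Kyte-Doolittle hydropathy values (one-letter keys).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9,
    "A": 1.8, "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3,
    "P": -1.6, "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5,
    "K": -3.9, "R": -4.5,
}

#: residues whose side-chain N/O/S atoms count as H-bond donors/acceptors.
_HBOND_SIDECHAIN_RESIDUES = {
    "SER", "THR", "TYR", "ASN", "GLN", "ASP", "GLU",
    "LYS", "ARG", "HIS", "TRP", "CYS", "MET",
}
_BACKBONE_HBOND_ATOMS = {"N", "O", "OXT"}

#: coarse integer side-chain charges distributed over terminal atoms.
#: Deliberately crude stand-in; DX grid ingestion is the fidelity path.
CHARGE_TABLE = {
    "ARG": (["NH1", "NH2"], +1.0),
    "LYS": (["NZ"], +1.0),
    "ASP": (["OD1", "OD2"], -1.0),
    "GLU": (["OE1", "OE2"], -1.0),
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "SOL"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom from a structure file."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_seq: int
    position: np.ndarray  # (3,) angstrom
    element: str

    @property
    def is_standard(self) -> bool:
        return self.residue_name in THREE_TO_ONE


@dataclass
class ProteinStructure:
    """Flat atom list plus per-chain one-letter sequences.

    ``residues`` lists distinct ``(chain, residue_seq, residue_name)``
    tuples in file order; ``atom_residue`` maps each atom to its index in
    that list.
    """

    atoms: list[AtomRecord]
    residues: list[tuple[str, int, str]]
    atom_residue: np.ndarray  # (n_atoms,) int index into residues

    @property
    def sequence(self) -> dict[str, str]:
        seqs: dict[str, str] = {}
        for chain, _seq, name in self.residues:
            seqs[chain] = seqs.get(chain, "") + THREE_TO_ONE.get(name, "X")
        return seqs

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class ScalarGrid:
    """Axis-aligned scalar grid (OpenDX layout, x-slowest)."""

    origin: np.ndarray   # (3,)
    spacing: np.ndarray  # (3,) per-axis step, > 0
    values: np.ndarray   # (nx, ny, nz)

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape

    def validate(self) -> None:
        if not np.all(self.spacing > 0):
            raise UnsupportedGridError("grid spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise UnsupportedGridError("grid contains non-finite values")


@dataclass
class SurfaceMesh:
    """Closed triangulated surface with per-triangle attribution and channels."""

    vertices: np.ndarray          # (V, 3)
    triangles: np.ndarray         # (T, 3) int
    triangle_area: np.ndarray     # (T,)
    triangle_normal: np.ndarray   # (T, 3) outward unit normals
    triangle_centroid: np.ndarray  # (T, 3)
    triangle_atom: np.ndarray | None = None      # (T,) source atom index
    triangle_residue: np.ndarray | None = None   # (T,) source residue index
    residue_names: list[str] | None = None       # 3-letter code per residue id
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    _neighbors: list[np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_map(self) -> dict[tuple[int, int], list[int]]:
        """Map sorted vertex pair -> triangle indices sharing that edge."""
        edges: dict[tuple[int, int], list[int]] = {}
        for t, (a, b, c) in enumerate(self.triangles):
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                edges.setdefault(key, []).append(t)
        return edges

    def triangle_neighbors(self) -> list[np.ndarray]:
        """Edge-adjacent triangle indices per triangle (cached)."""
        if self._neighbors is None:
            neigh: list[list[int]] = [[] for _ in range(self.n_triangles)]
            for tris in self.edge_map().values():
                for i in tris:
                    for j in tris:
                        if i != j:
                            neigh[i].append(j)
            self._neighbors = [np.array(sorted(set(n)), dtype=int)
                               for n in neigh]
        return self._neighbors

    def connected_components(self) -> np.ndarray:
        """Component label per triangle via edge adjacency."""
        labels = np.full(self.n_triangles, -1, dtype=int)
        neigh = self.triangle_neighbors()
        comp = 0
        for seed in range(self.n_triangles):
            if labels[seed] >= 0:
                continue
            stack = [seed]
            labels[seed] = comp
            while stack:
                t = stack.pop()
                for u in neigh[t]:
                    if labels[u] < 0:
                        labels[u] = comp
                        stack.append(int(u))
            comp += 1
        return labels

    @property
    def total_area(self) -> float:
        return float(self.triangle_area.sum())


def mesh_from_arrays(vertices: np.ndarray, triangles: np.ndarray,
                     orient_reference: np.ndarray | None = None,
                     **kwargs) -> SurfaceMesh:
    """Build a SurfaceMesh computing areas, centroids and outward normals.

    ``orient_reference``: per-triangle points normals should point away
    from (defaults to the mesh centroid for star-shaped meshes).
    """
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    v0 = vertices[triangles[:, 0]]
    v1 = vertices[triangles[:, 1]]
    v2 = vertices[triangles[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    norms = np.linalg.norm(cross, axis=1)
    if np.any(norms <= 0):
        raise DegenerateGeometryError("degenerate (zero-area) triangle")
    area = 0.5 * norms
    normal = cross / norms[:, None]
    centroid = (v0 + v1 + v2) / 3.0
    if orient_reference is None:
        orient_reference = vertices.mean(axis=0)[None, :]
    outward = centroid - orient_reference
    flip = np.einsum("ij,ij->i", normal, outward) < 0
    normal[flip] *= -1
    return SurfaceMesh(vertices=vertices, triangles=triangles,
                       triangle_area=area, triangle_normal=normal,
                       triangle_centroid=centroid, **kwargs)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if len(stripped) >= 2 and stripped[:2].upper() in VDW_RADII:
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_pdb(path) -> ProteinStructure:
    """Parse ATOM/HETATM records of the first model of a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters are excluded.
    """
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise FormatError(f"cannot read PDB file {path!r}: {exc}") from exc

    # (chain, resseq, atom name) -> (occupancy, AtomRecord); keeps the
    # highest-occupancy altloc, first wins on ties.
    best: dict[tuple, tuple[float, int, AtomRecord]] = {}
    order = 0
    in_model = 0
    for line in lines:
        rec = line[:6]
        if rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            if resname in _WATER_NAMES:
                continue
            serial = int(line[6:11])
            chain = line[21].strip() or "A"
            resseq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occ = float(occ_field) if occ_field else 1.0
            elem_field = line[76:78].strip() if len(line) >= 78 else ""
            element = elem_field.upper() or _guess_element(name)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"malformed PDB record: {line.rstrip()!r}") from exc
        pos = np.array([x, y, z], dtype=float)
        if not np.all(np.isfinite(pos)):
            raise FormatError(f"non-finite coordinates: {line.rstrip()!r}")
        atom = AtomRecord(serial=serial, name=name, residue_name=resname,
                          chain=chain, residue_seq=resseq, position=pos,
                          element=element)
        key = (chain, resseq, resname, name)
        if key not in best or occ > best[key][0]:
            prev_order = best[key][1] if key in best else order
            best[key] = (occ, prev_order, atom)
        order += 1

    records = sorted(best.values(), key=lambda t: t[1])
    atoms = [rec for _occ, _ord, rec in records]
    if not atoms:
        raise EmptyStructureError(f"no non-water atoms in {path!r}")

    residues: list[tuple[str, int, str]] = []
    res_index: dict[tuple[str, int, str], int] = {}
    atom_residue = np.empty(len(atoms), dtype=int)
    for i, a in enumerate(atoms):
        key = (a.chain, a.residue_seq, a.residue_name)
        if key not in res_index:
            res_index[key] = len(residues)
            residues.append(key)
        atom_residue[i] = res_index[key]
    return ProteinStructure(atoms=atoms, residues=residues,
                            atom_residue=atom_residue)


def pdb_string(structure: ProteinStructure) -> str:
    """Render a minimal single-model PDB file as text."""
    lines = []
    for a in structure.atoms:
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain:1s}{a.residue_seq:4d}    "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: ProteinStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write(pdb_string(structure))


# ---------------------------------------------------------------------------
# OpenDX grids
# ---------------------------------------------------------------------------

def read_dx(path) -> ScalarGrid:
    """Read an OpenDX scalar grid (APBS dialect, z-fastest data order)."""
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise FormatError(f"cannot read DX file {path!r}: {exc}") from exc

    counts = None
    origin = None
    deltas: list[np.ndarray] = []
    values: list[float] = []
    n_items = None
    in_data = False
    for line in lines:
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("object") and "gridpositions" in s:
            toks = s.split()
            counts = tuple(int(t) for t in toks[-3:])
            continue
        if s.startswith("origin"):
            origin = np.array([float(t) for t in s.split()[1:4]])
            continue
        if s.startswith("delta"):
            deltas.append(np.array([float(t) for t in s.split()[1:4]]))
            continue
        if s.startswith("object") and "class array" in s:
            toks = s.split()
            if "items" in toks:
                n_items = int(toks[toks.index("items") + 1])
            in_data = True
            continue
        if s.startswith(("attribute", "component", "object", "end")):
            in_data = False
            continue
        if in_data:
            values.extend(float(t) for t in s.split())

    if counts is None or origin is None:
        raise UnsupportedGridError(f"{path!r}: missing gridpositions/origin")
    if len(deltas) != 3:
        raise UnsupportedGridError(
            f"{path!r}: expected 3 delta records, found {len(deltas)}")
    delta = np.vstack(deltas)
    if not np.allclose(delta, np.diag(np.diag(delta))):
        raise UnsupportedGridError(f"{path!r}: sheared (non-axis-aligned) grid")
    spacing = np.diag(delta).copy()
    if not np.all(spacing > 0):
        raise UnsupportedGridError(f"{path!r}: non-positive grid spacing")
    n_expected = counts[0] * counts[1] * counts[2]
    if n_items is not None and n_items != n_expected:
        raise UnsupportedGridError(
            f"{path!r}: item count {n_items} != product of counts {n_expected}")
    if len(values) != n_expected:
        raise UnsupportedGridError(
            f"{path!r}: {len(values)} values, expected {n_expected}")
    arr = np.array(values, dtype=float).reshape(counts)  # C order = z fastest
    grid = ScalarGrid(origin=origin, spacing=spacing, values=arr)
    grid.validate()
    return grid


def write_dx(grid: ScalarGrid, path, comment: str = "mtdminer grid") -> None:
    """Write a scalar grid in the OpenDX dialect read by :func:`read_dx`."""
    nx, ny, nz = grid.counts
    flat = grid.values.reshape(-1)
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {grid.spacing[1]:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {grid.spacing[2]:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} "
                 "data follows\n")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


# ---------------------------------------------------------------------------
# OFF meshes
# ---------------------------------------------------------------------------

def read_off(path) -> SurfaceMesh:
    """Read a triangle mesh in OFF format."""
    with open(path) as fh:
        tokens: list[str] = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path!r}: missing OFF header")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4  # skip edge count
    verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise FormatError(f"{path!r}: non-triangular face (size {k})")
        faces.append([int(t) for t in tokens[pos + 1:pos + 4]])
        pos += 1 + k
    return mesh_from_arrays(verts, np.array(faces, dtype=int))


def write_off(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {mesh.n_triangles} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


# ---------------------------------------------------------------------------
# surface construction
# ---------------------------------------------------------------------------

def _atom_radii(structure: ProteinStructure) -> np.ndarray:
    return np.array([VDW_RADII.get(a.element, DEFAULT_VDW)
                     for a in structure.atoms])


def build_surface(structure: ProteinStructure, probe_radius: float = 1.4,
                  grid_spacing: float = 0.6) -> SurfaceMesh:
    """Triangulate the probe-inflated molecular surface by marching cubes.

    The surface is the zero level set of ``min_i(|p - c_i| - (r_i + probe))``
    sampled on a regular grid; each triangle is attributed to the nearest
    atom center and its residue.
    """
    from skimage.measure import marching_cubes

    if len(structure) == 0:
        raise EmptyStructureError("empty structure")
    coords = structure.coords
    radii = _atom_radii(structure) + probe_radius
    if len(coords) > 1 and np.ptp(coords, axis=0).max() < 1e-9:
        raise DegenerateGeometryError("all atoms coincident")

    pad = radii.max() + 3 * grid_spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    ns = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    axes = [lo[d] + grid_spacing * np.arange(ns[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    # signed distance to union of inflated atom spheres, chunked for memory
    fieldv = np.empty(len(pts))
    chunk = 200_000
    for s in range(0, len(pts), chunk):
        d = np.linalg.norm(pts[s:s + chunk, None, :] - coords[None, :, :],
                           axis=2)
        fieldv[s:s + chunk] = (d - radii[None, :]).min(axis=1)
    volume = fieldv.reshape(tuple(ns))

    if volume.min() > 0 or volume.max() < 0:
        raise DegenerateGeometryError("level set empty; check radii/spacing")
    verts, faces, _normals, _vals = marching_cubes(
        volume, level=0.0, spacing=(grid_spacing,) * 3)
    verts = verts + lo

    v0, v1, v2 = (verts[faces[:, i]] for i in range(3))
    cross = np.cross(v1 - v0, v2 - v0)
    norms = np.linalg.norm(cross, axis=1)
    keep = norms > 1e-12
    faces = faces[keep]
    cross = cross[keep]
    norms = norms[keep]
    area = 0.5 * norms
    normal = cross / norms[:, None]
    centroid = (verts[faces[:, 0]] + verts[faces[:, 1]] + verts[faces[:, 2]]) / 3.0

    tree = cKDTree(coords)
    _, nearest = tree.query(centroid)

    # orient outward: away from the sphere the triangle locally lies on
    d_all = np.linalg.norm(centroid[:, None, :] - coords[None, :, :], axis=2) \
        if len(coords) <= 512 else None
    if d_all is not None:
        owner = np.argmin(d_all - radii[None, :], axis=1)
    else:
        _, cand = tree.query(centroid, k=min(len(coords), 16))
        d = np.linalg.norm(centroid[:, None, :] - coords[cand], axis=2)
        owner = cand[np.arange(len(centroid)), np.argmin(d - radii[cand], axis=1)]
    outward = centroid - coords[owner]
    flip = np.einsum("ij,ij->i", normal, outward) < 0
    normal[flip] *= -1

    residue_names = [name for (_c, _s, name) in structure.residues]
    return SurfaceMesh(
        vertices=verts, triangles=faces, triangle_area=area,
        triangle_normal=normal, triangle_centroid=centroid,
        triangle_atom=nearest.astype(int),
        triangle_residue=structure.atom_residue[nearest],
        residue_names=residue_names)


# ---------------------------------------------------------------------------
# property mapping
# ---------------------------------------------------------------------------

def trilinear(grid: ScalarGrid, points: np.ndarray,
              clamp: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of ``grid`` at ``points``.

    Returns (values, in_bounds mask). Out-of-bounds points are clamped to
    the nearest in-bounds corner when ``clamp`` is set.
    """
    frac = (np.atleast_2d(points) - grid.origin) / grid.spacing
    nx, ny, nz = grid.counts
    upper = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
    in_bounds = np.all((frac >= 0) & (frac <= upper), axis=1)
    if clamp:
        frac = np.clip(frac, 0.0, upper)
    i0 = np.floor(frac).astype(int)
    i0 = np.minimum(i0, (np.array([nx, ny, nz]) - 2).clip(min=0))
    t = frac - i0
    i1 = np.minimum(i0 + 1, [nx - 1, ny - 1, nz - 1])
    v = grid.values
    x0, y0, z0 = i0.T
    x1, y1, z1 = i1.T
    tx, ty, tz = t.T
    out = (v[x0, y0, z0] * (1 - tx) * (1 - ty) * (1 - tz)
           + v[x1, y0, z0] * tx * (1 - ty) * (1 - tz)
           + v[x0, y1, z0] * (1 - tx) * ty * (1 - tz)
           + v[x0, y0, z1] * (1 - tx) * (1 - ty) * tz
           + v[x1, y1, z0] * tx * ty * (1 - tz)
           + v[x1, y0, z1] * tx * (1 - ty) * tz
           + v[x0, y1, z1] * (1 - tx) * ty * tz
           + v[x1, y1, z1] * tx * ty * tz)
    return out, in_bounds


def map_grid_to_surface(mesh: SurfaceMesh, grid: ScalarGrid,
                        offset: float = 1.0,
                        channel_name: str = "elec") -> SurfaceMesh:
    """Sample the grid at centroid + offset * normal per triangle.

    The sample is the trilinear (8-corner weighted) average at the probe
    point; probes outside the grid take the nearest in-bounds value and are
    reported in a warning. Geometry is left untouched.
    """
    probes = mesh.triangle_centroid + offset * mesh.triangle_normal
    values, in_bounds = trilinear(grid, probes, clamp=True)
    n_out = int((~in_bounds).sum())
    if n_out == mesh.n_triangles:
        raise MappingError("grid and mesh are spatially disjoint")
    if n_out:
        warnings.warn(
            f"{n_out}/{mesh.n_triangles} probe points outside grid; "
            "clamped to nearest in-bounds value", stacklevel=2)
    mesh.channels[channel_name] = values
    return mesh


def map_hydrophobicity(mesh: SurfaceMesh, structure: ProteinStructure,
                       channel_name: str = "kd") -> SurfaceMesh:
    """Kyte-Doolittle value of the residue that gave rise to each triangle."""
    if mesh.triangle_residue is None:
        raise MappingError("mesh lacks residue attribution")
    values = np.zeros(mesh.n_triangles)
    n_nonstd = 0
    for t, rid in enumerate(mesh.triangle_residue):
        resname = structure.residues[rid][2]
        one = THREE_TO_ONE.get(resname)
        if one is None:
            n_nonstd += 1
            continue
        values[t] = KYTE_DOOLITTLE[one]
    if n_nonstd:
        warnings.warn(f"{n_nonstd} triangles from non-standard residues "
                      "assigned hydrophobicity 0", stacklevel=2)
    mesh.channels[channel_name] = values
    return mesh


def is_hbond_capable(atom: AtomRecord) -> bool:
    """Donor/acceptor test: backbone N/O, side-chain N/O of polar residues,
    side-chain S of Cys/Met."""
    name = atom.name.strip()
    if name in _BACKBONE_HBOND_ATOMS:
        return True
    if atom.element in ("N", "O") and atom.residue_name in _HBOND_SIDECHAIN_RESIDUES:
        return True
    if atom.element == "S" and atom.residue_name in ("CYS", "MET"):
        return True
    return False


def map_hbond(mesh: SurfaceMesh, structure: ProteinStructure,
              channel_name: str = "hbond") -> SurfaceMesh:
    """Binary channel: 1 where the source atom can hydrogen bond."""
    if mesh.triangle_atom is None:
        raise MappingError("mesh lacks atom attribution")
    capable = np.array([is_hbond_capable(a) for a in structure.atoms],
                       dtype=float)
    mesh.channels[channel_name] = capable[mesh.triangle_atom]
    return mesh


# ---------------------------------------------------------------------------
# screened-Coulomb fallback grid
# ---------------------------------------------------------------------------

def atom_charges(structure: ProteinStructure) -> np.ndarray:
    """Coarse per-atom partial charges (integer side-chain charges spread
    over terminal atoms; falls back to CB/CA when those are absent)."""
    q = np.zeros(len(structure))
    by_residue: dict[int, list[int]] = {}
    for i, rid in enumerate(structure.atom_residue):
        by_residue.setdefault(int(rid), []).append(i)
    for rid, atom_ids in by_residue.items():
        resname = structure.residues[rid][2]
        if resname not in CHARGE_TABLE:
            continue
        carrier_names, total = CHARGE_TABLE[resname]
        carriers = [i for i in atom_ids
                    if structure.atoms[i].name.strip() in carrier_names]
        if not carriers:
            for fallback in ("CB", "CA"):
                carriers = [i for i in atom_ids
                            if structure.atoms[i].name.strip() == fallback]
                if carriers:
                    break
        if carriers:
            q[carriers] = total / len(carriers)
    return q


def coulomb_grid(structure: ProteinStructure, spacing: float = 1.0,
                 padding: float = 6.0, ionic_screening_length: float = 8.0,
                 dielectric: float = 80.0) -> ScalarGrid:
    """Screened Coulomb potential grid, a stand-in for an external PB solve.

    phi(p) = sum_i q_i exp(-d_i / lambda) / (4 pi eps d_i), d_i clamped at
    1 angstrom. ``ionic_screening_length`` of ``inf`` disables screening.
    """
    if len(structure) == 0:
        raise EmptyStructureError("empty structure")
    coords = structure.coords
    q = atom_charges(structure)
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    ns = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[d] + spacing * np.arange(ns[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    phi = np.zeros(len(pts))
    charged = np.nonzero(q)[0]
    lam = ionic_screening_length
    for i in charged:
        d = np.linalg.norm(pts - coords[i], axis=1)
        d = np.maximum(d, 1.0)
        screen = np.exp(-d / lam) if np.isfinite(lam) else 1.0
        phi += q[i] * screen / (4.0 * np.pi * dielectric * d)
    return ScalarGrid(origin=lo, spacing=np.full(3, float(spacing)),
                      values=phi.reshape(tuple(ns)))
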