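"""Synthetic fixtures with analytic ground truth.

Icospheres with planted same-value caps of known closed-form area
(2 pi R^2 (1 - cos theta)), two-class alignments with planted
position-specific residue preferences, tabular datasets labeled by known
threshold rules plus label noise, and toy extended-chain protein
structures. Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .seqfeat import AA_ALPHABET, LabeledAlignment
from .structio import (AtomRecord, ProteinStructure, SurfaceMesh,
                       mesh_from_arrays)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# icosphere meshes with planted caps
# ---------------------------------------------------------------------------

def icosphere(subdivisions: int = 3, radius: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Vertices and faces of a subdivided icosahedron on a sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=int)

    for _ in range(subdivisions):
        verts_list = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                m = (verts_list[a] + verts_list[b]) / 2.0
                m /= np.linalg.norm(m)
                midpoint[key] = len(verts_list)
                verts_list.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc],
                          [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=int)
    return verts * radius, faces


@dataclass
class PlantedPatchSpec:
    mesh_subdivisions: int = 4
    radius: float = 1.0
    caps: list[tuple] = field(default_factory=list)
    # each cap: (center direction 3-vector, angular radius rad, value)
    background: float = 0.0
    channel: str = "planted"


def spherical_cap_area(radius: float, theta: float) -> float:
    """Closed-form cap area 2 pi R^2 (1 - cos theta)."""
    return 2.0 * np.pi * radius ** 2 * (1.0 - np.cos(theta))


def make_sphere_mesh(spec: PlantedPatchSpec) -> tuple[SurfaceMesh, list[float]]:
    """Icosphere with planted same-value caps; returns closed-form areas.

    Caps must be pairwise disjoint (angular separation of centers greater
    than the sum of angular radii).
    """
    dirs = [np.asarray(c[0], dtype=float) for c in spec.caps]
    dirs = [d / np.linalg.norm(d) for d in dirs]
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            sep = np.arccos(np.clip(dirs[i] @ dirs[j], -1, 1))
            if sep <= spec.caps[i][1] + spec.caps[j][1]:
                raise DataError(f"caps {i} and {j} overlap")

    verts, faces = icosphere(spec.mesh_subdivisions, spec.radius)
    mesh = mesh_from_arrays(verts, faces,
                            orient_reference=np.zeros((1, 3)))
    values = np.full(mesh.n_triangles, spec.background, dtype=float)
    unit_centroids = mesh.triangle_centroid / np.linalg.norm(
        mesh.triangle_centroid, axis=1)[:, None]
    for d, (_, theta, value) in zip(dirs, spec.caps):
        angles = np.arccos(np.clip(unit_centroids @ d, -1, 1))
        values[angles <= theta] = value
    mesh.channels[spec.channel] = values
    areas = [spherical_cap_area(spec.radius, c[1]) for c in spec.caps]
    return mesh, areas


# ---------------------------------------------------------------------------
# labeled alignments with planted motifs
# ---------------------------------------------------------------------------

@dataclass
class MotifSpec:
    L: int = 80
    n_plus: int = 20
    n_minus: int = 20
    # each window: (start, length, plus distribution, minus distribution);
    # distributions are length-20 vectors over AA_ALPHABET applied per column
    windows: list[tuple] = field(default_factory=list)
    background: np.ndarray | None = None  # length-20, default uniform
    seed: int = 0

    def __post_init__(self) -> None:
        spans = sorted((w[0], w[0] + w[1]) for w in self.windows)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise DataError("motif windows overlap")
        for s, e in spans:
            if s < 0 or e > self.L:
                raise DataError("motif window outside alignment")
        for w in self.windows:
            if not 3 <= w[1] <= 6:
                raise DataError("motif window length must be in [3, 6]")


def peaked_distribution(residue: str, weight: float = 0.6) -> np.ndarray:
    """Distribution putting ``weight`` on one residue, rest uniform."""
    dist = np.full(20, (1.0 - weight) / 19.0)
    dist[AA_ALPHABET.index(residue)] = weight
    return dist


def make_labeled_alignment(spec: MotifSpec) -> LabeledAlignment:
    """Sample rows i.i.d. per column from class/window distributions."""
    rng = np.random.default_rng(spec.seed)
    background = (np.full(20, 1.0 / 20.0) if spec.background is None
                  else np.asarray(spec.background, dtype=float))
    if not np.isclose(background.sum(), 1.0):
        raise DataError("background distribution must sum to 1")

    def sample_class(n: int, plus: bool) -> list[str]:
        col_dists = [background] * spec.L
        for start, length, dplus, dminus in spec.windows:
            d = np.asarray(dplus if plus else dminus, dtype=float)
            if not np.isclose(d.sum(), 1.0):
                raise DataError("window distribution must sum to 1")
            for c in range(start, start + length):
                col_dists[c] = d
        rows = []
        for _ in range(n):
            chars = [AA_ALPHABET[rng.choice(20, p=col_dists[c])]
                     for c in range(spec.L)]
            rows.append("".join(chars))
        return rows

    plus_rows = sample_class(spec.n_plus, True)
    minus_rows = sample_class(spec.n_minus, False)
    names = [f"pos_{i}" for i in range(spec.n_plus)] + \
            [f"neg_{i}" for i in range(spec.n_minus)]
    return LabeledAlignment(
        names=names, rows=plus_rows + minus_rows,
        labels=np.concatenate([np.ones(spec.n_plus, dtype=int),
                               np.zeros(spec.n_minus, dtype=int)]))


# ---------------------------------------------------------------------------
# rule-labeled tabular datasets
# ---------------------------------------------------------------------------

@dataclass
class RuleDatasetSpec:
    n: int = 300
    d: int = 25
    # each rule: (feature index, threshold, vote); clean label is the sign
    # of the summed votes. Default: a staircase concept (two thresholds on
    # feature 0, one on feature 1) that both tree and kernel learners can
    # recover near the Bayes rate at n=300.
    rules: list[tuple] | None = None
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise < 0.5:
            raise DataError("noise rate must be in [0, 0.5)")
        if self.rules is None:
            self.rules = [(0, 0.3, 1.0), (0, 0.7, 1.0), (1, 0.5, 1.0)]
        for f, _t, _v in self.rules:
            if not 0 <= f < self.d:
                raise DataError("rule feature index out of range")


def make_rule_dataset(spec: RuleDatasetSpec) -> tuple[np.ndarray, np.ndarray, list[tuple], float]:
    """Uniform features labeled by voting threshold rules plus label noise.

    Returns (X, y, rules, bayes_accuracy); y is {0, 1} and
    bayes_accuracy = 1 - noise.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(size=(spec.n, spec.d))
    votes = np.zeros(spec.n)
    for f, thr, vote in spec.rules:
        votes += np.where(X[:, f] > thr, vote, -vote)
    y = (votes > 0).astype(int)
    flip = rng.uniform(size=spec.n) < spec.noise
    y = np.where(flip, 1 - y, y)
    return X, y, list(spec.rules), 1.0 - spec.noise


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

#: side-chain tip atom used for the pseudo side chain of each residue type;
#: charged residues get their real terminal atom so the coarse charge table
#: applies naturally.
_TIP_ATOM = {"ARG": "NH1", "LYS": "NZ", "ASP": "OD1", "GLU": "OE1"}


def make_toy_structure(n_residues: int, composition: str | None = None,
                       seed: int = 0) -> tuple[ProteinStructure, str]:
    """Extended-chain toy structure; returns the structure and PDB text.

    Each residue contributes backbone N, CA, C, O plus one pseudo
    side-chain atom (CB, or the charge-bearing tip for D/E/K/R); glycine
    has no side-chain atom.
    """
    from .structio import pdb_string

    if n_residues < 1:
        raise DataError("need at least one residue")
    rng = np.random.default_rng(seed)
    if composition is None:
        composition = "".join(rng.choice(list(AA_ALPHABET), size=n_residues))
    if len(composition) != n_residues:
        raise DataError("composition length != n_residues")

    atoms: list[AtomRecord] = []
    residues: list[tuple[str, int, str]] = []
    atom_residue: list[int] = []
    serial = 1
    for i, one in enumerate(composition.upper()):
        three = ONE_TO_THREE.get(one)
        if three is None:
            raise DataError(f"unknown residue code {one!r}")
        x0 = 3.8 * i
        zig = 0.5 if i % 2 else -0.5
        local = [
            ("N", "N", (-1.2, 0.4, zig)),
            ("CA", "C", (0.0, 0.0, zig)),
            ("C", "C", (1.2, 0.4, zig)),
            ("O", "O", (1.3, 1.6, zig)),
        ]
        if three != "GLY":
            tip = _TIP_ATOM.get(three, "CB")
            local.append((tip, tip[0], (0.0, -1.5, zig + 0.3)))
        residues.append(("A", i + 1, three))
        for name, element, (dx, dy, dz) in local:
            atoms.append(AtomRecord(
                serial=serial, name=name, residue_name=three, chain="A",
                residue_seq=i + 1,
                position=np.array([x0 + dx, dy, dz]), element=element))
            atom_residue.append(i)
            serial += 1

    structure = ProteinStructure(atoms=atoms, residues=residues,
                                 atom_residue=np.array(atom_residue))
    return structure, pdb_string(structure)
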