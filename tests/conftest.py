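import numpy as np
import pytest

from mtdminer import synthgen
from mtdminer.structio import (AtomRecord, ProteinStructure, build_surface,
                               mesh_from_arrays)


@pytest.fixture(scope="session")
def carbon_structure():
    atom = AtomRecord(serial=1, name="CA", residue_name="ALA", chain="A",
                      residue_seq=1, position=np.zeros(3), element="C")
    return ProteinStructure(atoms=[atom], residues=[("A", 1, "ALA")],
                            atom_residue=np.array([0]))


@pytest.fixture(scope="session")
def carbon_mesh(carbon_structure):
    return build_surface(carbon_structure)


@pytest.fixture(scope="session")
def toy_structure():
    structure, pdb_text = synthgen.make_toy_structure(6, "ARKDEW", seed=1)
    return structure, pdb_text


@pytest.fixture
def toy_pdb(tmp_path, toy_structure):
    path = tmp_path / "toy.pdb"
    path.write_text(toy_structure[1])
    return path


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit icosphere (subdiv 3, 1280 triangles) without planted channels."""
    verts, faces = synthgen.icosphere(3, 1.0)
    return mesh_from_arrays(verts, faces, orient_reference=np.zeros((1, 3)))


def make_attributed_sphere(residue_names, subdiv=2, seed=0):
    """Icosphere whose triangles are attributed round-robin to the given
    residues (one pseudo-atom per residue)."""
    verts, faces = synthgen.icosphere(subdiv, 1.0)
    mesh = mesh_from_arrays(verts, faces, orient_reference=np.zeros((1, 3)))
    n = mesh.n_triangles
    rng = np.random.default_rng(seed)
    rid = rng.integers(0, len(residue_names), size=n)
    mesh.triangle_atom = rid.copy()
    mesh.triangle_residue = rid
    mesh.residue_names = list(residue_names)
    return mesh


def union_find_partition(mesh, values, accept):
    """Independent union-find over all mesh edges with predicate ``accept``.

    Returns a canonical partition: root label per triangle.
    """
    parent = list(range(mesh.n_triangles))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for tris in mesh.edge_map().values():
        for i in range(len(tris)):
            for j in range(i + 1, len(tris)):
                a, b = tris[i], tris[j]
                if accept(values[a], values[b]):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[ra] = rb
    return np.array([find(t) for t in range(mesh.n_triangles)])


def partition_from_patches(patches_list, n):
    labels = np.full(n, -1, dtype=int)
    for k, p in enumerate(patches_list):
        labels[p.triangle_ids] = k
    return labels


def same_partition(labels_a, labels_b):
    """True iff two labelings induce identical partitions."""
    seen = {}
    for a, b in zip(labels_a, labels_b):
        if a in seen:
            if seen[a] != b:
                return False
        else:
            seen[a] = b
    return len(set(seen.values())) == len(seen)
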