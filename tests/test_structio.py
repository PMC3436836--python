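import numpy as np
import pytest

from mtdminer import structio
from mtdminer.errors import (DegenerateGeometryError, EmptyStructureError,
                             MappingError, UnsupportedGridError)
from mtdminer.structio import (AtomRecord, ProteinStructure, ScalarGrid,
                               build_surface, coulomb_grid, map_grid_to_surface,
                               map_hbond, map_hydrophobicity, mesh_from_arrays,
                               read_dx, read_off, read_pdb, trilinear,
                               write_dx, write_off)

from conftest import make_attributed_sphere


def _pdb_line(serial, name, resname, resseq, x, y, z, occ=1.0, record="ATOM  ",
              altloc=" ", element=None):
    element = element or name[0]
    return (f"{record}{serial:5d}  {name:<3s}{altloc}{resname:>3s} A{resseq:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          "
            f"{element:>2s}\n")


def _three_residue_pdb():
    """3 residues x 8 atoms = 24 atoms."""
    names = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]
    lines = []
    serial = 1
    for r, resname in enumerate(["ALA", "GLY", "LYS"], start=1):
        for i, name in enumerate(names):
            lines.append(_pdb_line(serial, name, resname, r,
                                   3.8 * r + 0.3 * i, 0.5 * i, 0.1 * serial))
            serial += 1
    return "".join(lines) + "END\n"


class TestReadPdb:
    def test_hand_written_24_atoms(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(_three_residue_pdb())
        structure = read_pdb(p)
        assert len(structure) == 24
        assert len(structure.residues) == 3
        assert structure.sequence == {"A": "AGK"}

    def test_two_models_first_only(self, tmp_path):
        body = "MODEL     1\n" + _pdb_line(1, "CA", "ALA", 1, 0, 0, 0) \
            + "ENDMDL\nMODEL     2\n" \
            + _pdb_line(2, "CA", "ALA", 1, 9, 9, 9) + "ENDMDL\nEND\n"
        p = tmp_path / "models.pdb"
        p.write_text(body)
        structure = read_pdb(p)
        assert len(structure) == 1
        np.testing.assert_allclose(structure.atoms[0].position, [0, 0, 0])

    def test_water_only_is_empty(self, tmp_path):
        body = _pdb_line(1, "O", "HOH", 1, 0, 0, 0, record="HETATM")
        p = tmp_path / "water.pdb"
        p.write_text(body)
        with pytest.raises(EmptyStructureError):
            read_pdb(p)

    def test_altloc_highest_occupancy(self, tmp_path):
        body = (_pdb_line(1, "CA", "ALA", 1, 0, 0, 0, occ=0.4, altloc="A")
                + _pdb_line(2, "CA", "ALA", 1, 5, 5, 5, occ=0.6, altloc="B")
                + "END\n")
        p = tmp_path / "alt.pdb"
        p.write_text(body)
        structure = read_pdb(p)
        assert len(structure) == 1
        np.testing.assert_allclose(structure.atoms[0].position, [5, 5, 5])


class TestDx:
    def test_hand_written_2x2x2(self, tmp_path):
        text = (
            "object 1 class gridpositions counts 2 2 2\n"
            "origin 0.0 0.0 0.0\n"
            "delta 1.0 0.0 0.0\n"
            "delta 0.0 1.0 0.0\n"
            "delta 0.0 0.0 1.0\n"
            "object 2 class gridconnections counts 2 2 2\n"
            "object 3 class array type double rank 0 items 8 data follows\n"
            "0 1 2\n3 4 5\n6 7\n")
        p = tmp_path / "g.dx"
        p.write_text(text)
        grid = read_dx(p)
        assert grid.counts == (2, 2, 2)
        assert grid.values[1, 1, 1] == 7
        assert grid.values[0, 0, 1] == 1  # z fastest

    def test_missing_delta(self, tmp_path):
        text = (
            "object 1 class gridpositions counts 2 2 2\n"
            "origin 0.0 0.0 0.0\n"
            "delta 1.0 0.0 0.0\n"
            "delta 0.0 1.0 0.0\n"
            "object 3 class array type double rank 0 items 8 data follows\n"
            "0 1 2 3 4 5 6 7\n")
        p = tmp_path / "bad.dx"
        p.write_text(text)
        with pytest.raises(UnsupportedGridError):
            read_dx(p)

    def test_sheared_delta(self, tmp_path):
        text = (
            "object 1 class gridpositions counts 2 2 2\n"
            "origin 0.0 0.0 0.0\n"
            "delta 1.0 0.2 0.0\n"
            "delta 0.0 1.0 0.0\n"
            "delta 0.0 0.0 1.0\n"
            "object 3 class array type double rank 0 items 8 data follows\n"
            "0 1 2 3 4 5 6 7\n")
        p = tmp_path / "shear.dx"
        p.write_text(text)
        with pytest.raises(UnsupportedGridError):
            read_dx(p)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = ScalarGrid(origin=np.array([-1.0, 2.0, 0.5]),
                          spacing=np.array([0.5, 0.7, 1.1]),
                          values=rng.normal(size=(4, 5, 3)))
        p = tmp_path / "rt.dx"
        write_dx(grid, p)
        back = read_dx(p)
        np.testing.assert_allclose(back.values, grid.values, atol=1e-6)
        np.testing.assert_allclose(back.origin, grid.origin, atol=1e-6)
        np.testing.assert_allclose(back.spacing, grid.spacing, atol=1e-6)


def _euler_per_component(mesh):
    labels = mesh.connected_components()
    chis = []
    for comp in np.unique(labels):
        tris = mesh.triangles[labels == comp]
        V = len(np.unique(tris))
        F = len(tris)
        edges = set()
        for a, b, c in tris:
            for u, v in ((a, b), (b, c), (c, a)):
                edges.add((u, v) if u < v else (v, u))
        chis.append(V - len(edges) + F)
    return chis


class TestBuildSurface:
    def test_single_carbon_sphere_area(self, carbon_mesh):
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert abs(carbon_mesh.total_area - expected) / expected < 0.05

    def test_euler_characteristic(self, carbon_mesh):
        assert _euler_per_component(carbon_mesh) == [2]

    def test_normals_unit_and_outward(self, carbon_mesh):
        norms = np.linalg.norm(carbon_mesh.triangle_normal, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)
        radial = carbon_mesh.triangle_centroid / np.linalg.norm(
            carbon_mesh.triangle_centroid, axis=1)[:, None]
        dots = np.einsum("ij,ij->i", carbon_mesh.triangle_normal, radial)
        assert (dots > 0).all()

    def test_adjacency_symmetric_interior_edges(self, carbon_mesh):
        neigh = carbon_mesh.triangle_neighbors()
        for t, ns in enumerate(neigh):
            for u in ns:
                assert t in neigh[u]
        for tris in carbon_mesh.edge_map().values():
            assert len(tris) == 2

    def test_two_far_atoms_two_components(self):
        atoms = [AtomRecord(1, "CA", "ALA", "A", 1, np.zeros(3), "C"),
                 AtomRecord(2, "CA", "ALA", "A", 2,
                            np.array([30.0, 0, 0]), "C")]
        structure = ProteinStructure(
            atoms=atoms, residues=[("A", 1, "ALA"), ("A", 2, "ALA")],
            atom_residue=np.array([0, 1]))
        mesh = build_surface(structure, grid_spacing=0.8)
        labels = mesh.connected_components()
        assert labels.max() + 1 == 2
        assert sorted(_euler_per_component(mesh)) == [2, 2]

    def test_coincident_atoms_degenerate(self):
        atoms = [AtomRecord(i, "CA", "ALA", "A", i, np.zeros(3), "C")
                 for i in (1, 2)]
        structure = ProteinStructure(
            atoms=atoms, residues=[("A", 1, "ALA"), ("A", 2, "ALA")],
            atom_residue=np.array([0, 0]))
        with pytest.raises(DegenerateGeometryError):
            build_surface(structure)

    def test_area_converges_with_spacing(self, carbon_structure):
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        err = []
        for spacing in (0.9, 0.45):
            mesh = build_surface(carbon_structure, grid_spacing=spacing)
            err.append(abs(mesh.total_area - expected) / expected)
        assert err[1] < err[0]


def _oracle_trilinear(grid, p):
    """Independent direct 8-corner formula (scalar, no vectorization)."""
    fx = (p[0] - grid.origin[0]) / grid.spacing[0]
    fy = (p[1] - grid.origin[1]) / grid.spacing[1]
    fz = (p[2] - grid.origin[2]) / grid.spacing[2]
    ix, iy, iz = int(np.floor(fx)), int(np.floor(fy)), int(np.floor(fz))
    tx, ty, tz = fx - ix, fy - iy, fz - iz
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((tx if dx else 1 - tx) * (ty if dy else 1 - ty)
                     * (tz if dz else 1 - tz))
                total += w * grid.values[ix + dx, iy + dy, iz + dz]
    return total


class TestMapGridToSurface:
    @pytest.fixture
    def grid(self):
        rng = np.random.default_rng(1)
        return ScalarGrid(origin=np.array([-8.0, -8.0, -8.0]),
                          spacing=np.array([1.0, 1.0, 1.0]),
                          values=rng.normal(size=(17, 17, 17)))

    def test_constant_grid(self, carbon_mesh):
        grid = ScalarGrid(origin=np.full(3, -8.0), spacing=np.ones(3),
                          values=np.full((17, 17, 17), 3.25))
        map_grid_to_surface(carbon_mesh, grid, channel_name="const")
        np.testing.assert_allclose(carbon_mesh.channels["const"], 3.25)

    def test_linear_field_exact(self, carbon_mesh):
        xs = -8.0 + np.arange(17)
        vals = np.broadcast_to(xs[:, None, None], (17, 17, 17)).copy()
        grid = ScalarGrid(origin=np.full(3, -8.0), spacing=np.ones(3),
                          values=vals)
        map_grid_to_surface(carbon_mesh, grid, channel_name="lin")
        probes = carbon_mesh.triangle_centroid + carbon_mesh.triangle_normal
        np.testing.assert_allclose(carbon_mesh.channels["lin"], probes[:, 0],
                                   atol=1e-9)

    def test_matches_independent_oracle(self, grid):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-7.5, 7.5, size=(100, 3))
        values, in_bounds = trilinear(grid, pts)
        assert in_bounds.all()
        expected = np.array([_oracle_trilinear(grid, p) for p in pts])
        np.testing.assert_allclose(values, expected, atol=1e-12, rtol=0)

    def test_disjoint_grid_raises(self, carbon_mesh):
        grid = ScalarGrid(origin=np.full(3, 100.0), spacing=np.ones(3),
                          values=np.zeros((3, 3, 3)))
        with pytest.raises(MappingError):
            map_grid_to_surface(carbon_mesh, grid, channel_name="x")

    def test_geometry_untouched(self, carbon_mesh, grid):
        before = (carbon_mesh.vertices.copy(), carbon_mesh.triangles.copy(),
                  carbon_mesh.triangle_area.copy(),
                  carbon_mesh.triangle_normal.copy())
        map_grid_to_surface(carbon_mesh, grid, channel_name="g")
        assert (carbon_mesh.vertices == before[0]).all()
        assert (carbon_mesh.triangles == before[1]).all()
        assert (carbon_mesh.triangle_area == before[2]).all()
        assert (carbon_mesh.triangle_normal == before[3]).all()


class TestPropertyChannels:
    def test_all_ile(self, carbon_structure):
        mesh = make_attributed_sphere(["ILE"])
        structure = ProteinStructure(
            atoms=carbon_structure.atoms, residues=[("A", 1, "ILE")],
            atom_residue=np.array([0]))
        map_hydrophobicity(mesh, structure)
        np.testing.assert_allclose(mesh.channels["kd"], 4.5)

    def test_all_arg(self, carbon_structure):
        mesh = make_attributed_sphere(["ARG"])
        structure = ProteinStructure(
            atoms=carbon_structure.atoms, residues=[("A", 1, "ARG")],
            atom_residue=np.array([0]))
        map_hydrophobicity(mesh, structure)
        np.testing.assert_allclose(mesh.channels["kd"], -4.5)

    def test_gly_ala_two_values(self):
        mesh = make_attributed_sphere(["GLY", "ALA"])
        atoms = [AtomRecord(1, "CA", "GLY", "A", 1, np.zeros(3), "C"),
                 AtomRecord(2, "CA", "ALA", "A", 2, np.ones(3), "C")]
        structure = ProteinStructure(
            atoms=atoms, residues=[("A", 1, "GLY"), ("A", 2, "ALA")],
            atom_residue=np.array([0, 1]))
        map_hydrophobicity(mesh, structure)
        assert len(np.unique(mesh.channels["kd"])) == 2

    def test_hbond_table(self):
        atoms = [AtomRecord(1, "CB", "ALA", "A", 1, np.zeros(3), "C"),
                 AtomRecord(2, "O", "ALA", "A", 1, np.ones(3), "O")]
        structure = ProteinStructure(
            atoms=atoms, residues=[("A", 1, "ALA")],
            atom_residue=np.array([0, 0]))
        mesh = make_attributed_sphere(["ALA"])
        mesh.triangle_atom = np.arange(mesh.n_triangles) % 2
        map_hbond(mesh, structure)
        hb = mesh.channels["hbond"]
        assert set(np.unique(hb)) <= {0.0, 1.0}
        assert (hb[mesh.triangle_atom == 0] == 0).all()  # Ala CB carbon
        assert (hb[mesh.triangle_atom == 1] == 1).all()  # backbone carbonyl O


class TestCoulombGrid:
    def _one_charge(self):
        atom = AtomRecord(1, "NZ", "LYS", "A", 1, np.zeros(3), "N")
        return ProteinStructure(atoms=[atom], residues=[("A", 1, "LYS")],
                                atom_residue=np.array([0]))

    def test_unscreened_closed_form(self):
        structure = self._one_charge()
        grid = coulomb_grid(structure, spacing=1.0, padding=5.0,
                            ionic_screening_length=np.inf, dielectric=1.0)
        nx, ny, nz = grid.counts
        pts = (grid.origin[None, :]
               + grid.spacing * np.stack(np.meshgrid(
                   np.arange(nx), np.arange(ny), np.arange(nz),
                   indexing="ij"), axis=-1).reshape(-1, 3))
        d = np.maximum(np.linalg.norm(pts, axis=1), 1.0)
        expected = 1.0 / (4 * np.pi * d)
        np.testing.assert_allclose(grid.values.reshape(-1), expected,
                                   atol=1e-6)

    def test_charge_free_zero(self):
        atom = AtomRecord(1, "CA", "ALA", "A", 1, np.zeros(3), "C")
        structure = ProteinStructure(atoms=[atom], residues=[("A", 1, "ALA")],
                                     atom_residue=np.array([0]))
        grid = coulomb_grid(structure)
        assert (grid.values == 0).all()

    def test_mirror_symmetry(self):
        def struct(sign):
            atoms = [AtomRecord(1, "NZ", "LYS", "A", 1,
                                np.array([0.0, 0, 0]), "N"),
                     AtomRecord(2, "OE1", "GLU", "A", 2,
                                np.array([sign * 4.0, 0, 0]), "O")]
            return ProteinStructure(
                atoms=atoms, residues=[("A", 1, "LYS"), ("A", 2, "GLU")],
                atom_residue=np.array([0, 1]))

        ga = coulomb_grid(struct(+1), spacing=1.0, padding=3.0)
        gb = coulomb_grid(struct(-1), spacing=1.0, padding=3.0)
        np.testing.assert_allclose(gb.values, ga.values[::-1, :, :],
                                   atol=1e-9)

    def test_empty_structure(self):
        with pytest.raises(EmptyStructureError):
            coulomb_grid(ProteinStructure(atoms=[], residues=[],
                                          atom_residue=np.array([], dtype=int)))


class TestOff:
    def test_round_trip(self, tmp_path, sphere_mesh):
        p = tmp_path / "m.off"
        write_off(sphere_mesh, p)
        back = read_off(p)
        np.testing.assert_allclose(back.vertices, sphere_mesh.vertices,
                                   atol=1e-6)
        assert (back.triangles == sphere_mesh.triangles).all()
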