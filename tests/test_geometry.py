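"""Distances, CLRC search, cosines, dihedrals, ASA, secondary structure, Kabsch."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from disorderlink import (
    FamilyConfig,
    assign_ss3,
    backbone_dihedrals,
    build_seed_backbone,
    circular_stats,
    find_all_clrcs,
    find_clrc,
    kabsch_superpose,
    pair_cosines,
    relative_asa,
    residue_distance,
    shrake_rupley_asa,
    ss8_to_ss3,
)
from disorderlink.geometry import _sphere_points

from conftest import make_chain, make_residue


class TestResidueDistance:
    def test_identical_residues(self):
        a = make_residue(1, CB=(1, 2, 3))
        assert residue_distance(a, a) == 0.0

    def test_3_4_5_triangle(self):
        a = make_residue(1, CB=(0, 0, 0))
        b = make_residue(2, CB=(3, 4, 0))
        assert residue_distance(a, b) == pytest.approx(5.0)

    def test_gly_falls_back_to_ca(self):
        g = make_residue(1, "G", CA=(0, 0, 0))
        a = make_residue(2, "A", CB=(0, 0, 2), CA=(5, 5, 5))
        assert residue_distance(g, a) == pytest.approx(2.0)

    def test_missing_representative_atom(self):
        a = make_residue(1, N=(0, 0, 0))
        b = make_residue(2, CB=(1, 1, 1))
        assert residue_distance(a, b) is None

    @given(hst.lists(hst.tuples(*[hst.floats(-50, 50) for _ in range(3)]),
                     min_size=3, max_size=3))
    @settings(derandomize=True, max_examples=40)
    def test_symmetry_and_triangle_inequality(self, pts):
        r = [make_residue(i + 1, CB=p) for i, p in enumerate(pts)]
        d01 = residue_distance(r[0], r[1])
        d12 = residue_distance(r[1], r[2])
        d02 = residue_distance(r[0], r[2])
        assert d01 == pytest.approx(residue_distance(r[1], r[0]))
        assert d02 <= d01 + d12 + 1e-9


class TestCLRC:
    def test_separation_filter_decides(self):
        # residues 2-6 nearest in space but ineligible; residue 8 closest eligible
        coords = {2: 1.0, 3: 1.1, 4: 1.2, 5: 1.3, 6: 1.4,
                  7: 9.0, 8: 6.0, 9: 7.0, 10: 8.0, 11: 10.0, 12: 11.0}
        residues = [make_residue(1, CB=(0, 0, 0))]
        residues += [make_residue(n, CB=(d, 0, 0)) for n, d in coords.items()]
        chain = make_chain(residues)
        ca = find_clrc(chain, 0)
        assert chain.residues[ca.j].seq_num == 8
        assert ca.distance == pytest.approx(6.0)

    def test_straight_line_chain(self):
        # 3.8 A spacing: first eligible residue is #7 at 6 * 3.8 = 22.8 A
        residues = [make_residue(i + 1, CB=(3.8 * i, 0, 0)) for i in range(12)]
        chain = make_chain(residues)
        ca = find_clrc(chain, 0)
        assert chain.residues[ca.j].seq_num == 7
        assert ca.distance == pytest.approx(22.8)

    def test_exact_tie_takes_lowest_index(self):
        residues = [make_residue(1, CB=(0, 0, 0))]
        residues += [make_residue(n, CB=(50, 50, n)) for n in range(2, 9)]
        residues += [make_residue(9, CB=(7, 0, 0)), make_residue(10, CB=(50, 0, 0)),
                     make_residue(11, CB=(-7, 0, 0))]
        chain = make_chain(residues)
        ca = find_clrc(chain, 0)
        assert chain.residues[ca.j].seq_num == 9

    def test_no_eligible_residue(self):
        residues = [make_residue(i, CB=(i, 0, 0)) for i in range(1, 5)]
        assert find_clrc(make_chain(residues), 0) is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(20, 60))
            residues = [make_residue(i + 1, CB=tuple(rng.uniform(0, 30, 3)))
                        for i in range(n)]
            chain = make_chain(residues)
            contacts = find_all_clrcs(chain)
            for i in range(n):
                best, bestd = None, math.inf
                for j in range(n):
                    if abs(chain.residues[i].seq_num - chain.residues[j].seq_num) <= 5:
                        continue
                    d = residue_distance(chain.residues[i], chain.residues[j])
                    if d is not None and d < bestd:
                        best, bestd = j, d
                if best is None:
                    assert i not in contacts
                else:
                    assert contacts[i].j == best
                    assert contacts[i].distance == pytest.approx(bestd)


class TestPairCosines:
    def _res(self, seq, n, ca, c, cb=None, res_type="A"):
        kw = {"N": n, "CA": ca, "C": c}
        if cb is not None:
            kw["CB"] = cb
        return make_residue(seq, res_type, **kw)

    def test_identical_geometry_gives_ones(self):
        a = self._res(1, (0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 0, 1))
        b = self._res(9, (5, 5, 5), (6, 5, 5), (6, 6, 5), (6, 5, 6))
        pc = pair_cosines(a, b)
        assert (pc.c1, pc.c2, pc.c3) == pytest.approx((1.0, 1.0, 1.0))

    def test_antiparallel_nca(self):
        a = self._res(1, (0, 0, 0), (1, 0, 0), (1, 1, 0))
        b = self._res(9, (1, 5, 5), (0, 5, 5), (0, 6, 5))
        assert pair_cosines(a, b).c1 == pytest.approx(-1.0)

    def test_gly_zeroes_c3(self):
        a = self._res(1, (0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 0, 1))
        g = self._res(9, (5, 5, 5), (6, 5, 5), (6, 6, 5), res_type="G")
        assert pair_cosines(a, g).c3 == 0.0

    def test_degenerate_bond_vector(self):
        a = self._res(1, (0, 0, 0), (0, 0, 0), (1, 1, 0))
        b = self._res(9, (5, 5, 5), (6, 5, 5), (6, 6, 5))
        assert pair_cosines(a, b) is None


class TestDihedrals:
    def test_ideal_helix_torsions_recovered(self):
        cfg = FamilyConfig(length=120, seed=5)
        chain = build_seed_backbone(cfg)
        # interior of the first helix block (residues 1-40)
        for i in range(5, 30):
            phi, psi = backbone_dihedrals(chain, i)
            assert phi == pytest.approx(-57, abs=6)  # +-4 deg sampling jitter
            assert psi == pytest.approx(-47, abs=6)

    def test_first_residue_has_no_phi(self, seed_chain_50):
        phi, psi = backbone_dihedrals(seed_chain_50, 0)
        assert phi is None
        assert psi is not None

    def test_chain_break_suppresses_angles(self):
        residues = [
            make_residue(1, N=(0, 0, 0), CA=(1.4, 0, 0), C=(2.0, 1.3, 0)),
            make_residue(2, N=(3.3, 1.3, 0), CA=(4.0, 2.5, 0), C=(5.4, 2.5, 0)),
            make_residue(4, N=(20, 0, 0), CA=(21.4, 0, 0), C=(22, 1.3, 0)),
        ]
        chain = make_chain(residues)
        phi, psi = backbone_dihedrals(chain, 2)  # numbering gap before residue 4
        assert phi is None
        _, psi1 = backbone_dihedrals(chain, 1)  # break after residue 2
        assert psi1 is None


class TestCircularStats:
    def test_wraparound_mean(self):
        mean, _ = circular_stats([170.0, -170.0])
        assert abs(mean) == pytest.approx(180.0)

    def test_constant_angles(self):
        assert circular_stats([30.0, 30.0, 30.0]) == pytest.approx((30.0, 0.0))

    def test_sqrt_minus_2_ln_r(self):
        # Rbar = cos(45 deg); sd = sqrt(-2 ln Rbar) in degrees
        mean, sd = circular_stats([0.0, 90.0])
        assert mean == pytest.approx(45.0)
        expected = math.degrees(math.sqrt(-2.0 * math.log(math.cos(math.radians(45)))))
        assert sd == pytest.approx(expected, abs=1e-6)

    def test_agrees_with_arithmetic_mean_when_clustered(self):
        # circular-mean bias is O(spread^3); negligible for tightly clustered sets
        angles = [10.0, 10.3, 10.5, 10.1]
        mean, _ = circular_stats(angles)
        assert mean == pytest.approx(np.mean(angles), abs=1e-5)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            circular_stats([])


class TestASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        chain = make_chain([make_residue(1, CA=(0.0, 0.0, 0.0))])
        asa = shrake_rupley_asa(chain)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert asa[0] == pytest.approx(analytic, rel=0.02)

    def test_fully_overlapping_atoms(self):
        r = make_residue(1, CA=(0.0, 0.0, 0.0), C=(0.0, 0.0, 0.01))
        asa_two = shrake_rupley_asa(make_chain([r]))[0]
        asa_one = shrake_rupley_asa(make_chain([make_residue(1, CA=(0, 0, 0))]))[0]
        assert asa_two == pytest.approx(asa_one, rel=0.02)

    def test_deeply_buried_atom(self):
        # central atom caged by 12 icosahedron-vertex neighbours at 2 A
        phi = (1 + 5**0.5) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [(0, a, b), (a, b, 0), (b, 0, a)]
        verts = 2.0 * np.array(verts) / np.linalg.norm(verts[0])
        atoms = {"CA": np.zeros(3)}
        atoms.update({f"C{i}": v for i, v in enumerate(verts)})
        res = make_residue(1, **{k: tuple(v) if not np.isscalar(v) else v
                                 for k, v in atoms.items()})
        dense = shrake_rupley_asa(make_chain([res]), n_points=10000)
        fast = shrake_rupley_asa(make_chain([res]), n_points=960)
        # per-atom burial: compare the whole residue at two sampling densities
        assert fast[0] == pytest.approx(dense[0], rel=0.02)
        # the central atom itself contributes ~0: estimate via difference
        cage_only = make_residue(1, **{f"C{i}": tuple(v) for i, v in enumerate(verts)})
        cage_asa = shrake_rupley_asa(make_chain([cage_only]))[0]
        assert fast[0] - cage_asa < 0.05 * fast[0] + 5.0

    def test_rotation_invariance(self, seed_chain_50):
        from scipy.spatial.transform import Rotation

        asa = shrake_rupley_asa(seed_chain_50)
        R = Rotation.from_euler("xyz", [31, -57, 113], degrees=True).as_matrix()
        rotated = build_rotated(seed_chain_50, R, np.array([5.0, -3.0, 11.0]))
        asa_rot = shrake_rupley_asa(rotated)
        total, total_rot = sum(asa.values()), sum(asa_rot.values())
        assert total_rot == pytest.approx(total, rel=0.005)

    def test_cross_check_against_biotite(self, seed_chain_50):
        biotite = pytest.importorskip("biotite.structure")
        atoms = []
        import biotite.structure as struc

        arr = struc.AtomArray(sum(len(r.atoms) for r in seed_chain_50.residues))
        k = 0
        for i, res in enumerate(seed_chain_50.residues):
            for name, xyz in res.atoms.items():
                arr.coord[k] = xyz
                arr.atom_name[k] = name
                arr.element[k] = res.elements[name]
                arr.res_id[k] = res.seq_num
                arr.res_name[k] = "ALA"
                arr.chain_id[k] = "A"
                k += 1
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
        ours = shrake_rupley_asa(seed_chain_50)
        assert sum(ours.values()) == pytest.approx(float(np.nansum(ref)), rel=0.05)

    def test_sphere_points_on_unit_sphere(self):
        pts = _sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)


def build_rotated(chain, R, t):
    from disorderlink.structure_io import ChainStructure, ResidueStructure

    residues = []
    for res in chain.residues:
        atoms = {k: v @ R.T + t for k, v in res.atoms.items()}
        residues.append(ResidueStructure(res.chain_id, res.seq_num, res.icode,
                                         res.res_type, atoms, dict(res.elements)))
    return ChainStructure(chain.pdb_id, chain.chain_id, residues, list(chain.missing))


class TestRSA:
    def test_zero_and_max(self):
        assert relative_asa("A", 0.0) == 0.0
        assert relative_asa("A", 129.0) == pytest.approx(1.0)

    def test_ratio(self):
        assert relative_asa("A", 64.5) == pytest.approx(0.5)

    def test_unknown_type(self):
        assert relative_asa("X", 50.0) is None


class TestSS3:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-60, -45, "h"),
        (-120, 130, "e"),
        (75, 10, "c"),
        (None, -45, "c"),
    ])
    def test_regions(self, phi, psi, expected):
        assert assign_ss3(phi, psi) == expected

    def test_ideal_helix_and_strand_fixtures(self):
        cfg = FamilyConfig(length=120, seed=2)
        chain = build_seed_backbone(cfg)
        labels = [assign_ss3(*backbone_dihedrals(chain, i))
                  for i in range(len(chain.residues))]
        assert all(l == "h" for l in labels[2:38])   # first helix interior
        assert all(l == "e" for l in labels[45:51])  # first strand interior

    @pytest.mark.parametrize("ss8,ss3", [("H", "h"), ("G", "h"), ("I", "h"),
                                         ("E", "e"), ("B", "e"), ("T", "c"),
                                         ("S", "c"), ("C", "c")])
    def test_8_to_3_mapping(self, ss8, ss3):
        assert ss8_to_ss3(ss8) == ss3


class TestKabsch:
    def test_self_superposition(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(R, np.eye(3), atol=1e-6)

    def test_recovers_applied_rotation(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        Rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rot.T
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(R @ Rot, np.eye(3), atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_noisy_superposition_rmsd(self):
        rng = np.random.default_rng(2)
        P = rng.normal(scale=5, size=(50, 3))
        Q = P + rng.normal(scale=0.1, size=(50, 3))
        _, _, rmsd = kabsch_superpose(P, Q)
        assert 0.0 < rmsd < 0.2

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
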