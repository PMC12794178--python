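"""Topology construction: typing, term enumeration, exclusions, symmetry
classes, charge symmetrization and equivalent-term averaging."""
import numpy as np
import pytest

import rhcpff as r
from rhcpff.topology import (
    ChargeSet,
    average_equivalent_terms,
    enumerate_pairs,
    symmetrize_charges,
)


def _types(topo):
    return [a.atom_type for a in topo.atoms]


def _bond_sig(topo):
    t = _types(topo)
    return [tuple(sorted((t[b.i], t[b.j]))) for b in topo.bonds]


def _angle_sig(topo):
    t = _types(topo)
    out = []
    for a in topo.angles:
        s = (t[a.i], t[a.j], t[a.k])
        out.append(min(s, s[::-1]))
    return out


class TestTermEnumeration:
    def test_rh1_metal_bond_counts(self, rh1):
        """Five M1-Y1 and two M1-Y6 sigma bonds; no chloride bond in Rh(I)."""
        _, _, topo = rh1
        sigs = _bond_sig(topo)
        assert sigs.count(("M1", "Y1")) == 5
        assert sigs.count(("M1", "Y6")) == 2
        assert sigs.count(("M1", "Y8")) == 0

    def test_rh3_has_ten_n_metal_ring_angles(self, rh3):
        _, _, topo = rh3
        sigs = _angle_sig(topo)
        assert sigs.count(("Y1", "M1", "Y6")) == 10

    def test_all_metal_dihedrals_have_zero_barrier(self, rh1, rh3):
        for fix in (rh1, rh3):
            topo = fix[2]
            t = _types(topo)
            metal_dihedrals = [
                d
                for d in topo.dihedrals
                if "M1" in (t[d.i], t[d.j], t[d.k], t[d.l])
            ]
            assert metal_dihedrals  # they are present, not dropped
            assert all(d.barrier == 0.0 for d in metal_dihedrals)

    def test_oxidation_states_differ_by_chloride_terms_only(self, rh1, rh3):
        """Rh(III) adds exactly 1 bond (M1-Y8) and 7 angles (5 Y1-M1-Y8 +
        2 Y6-M1-Y8) on top of the Rh(I) topology."""
        t1, t3 = rh1[2], rh3[2]
        assert len(t3.bonds) - len(t1.bonds) == 1
        assert len(t3.angles) - len(t1.angles) == 7
        s3 = _angle_sig(t3)
        assert s3.count(("Y1", "M1", "Y8")) == 5
        assert s3.count(("Y6", "M1", "Y8")) == 2

    def test_exclusions_on_hand_enumerated_chain(self):
        # 0-1-2-3-4 chain: 1-2 and 1-3 neighbors excluded, 1-4 scaled
        excl, p14 = enumerate_pairs([(0, 1), (1, 2), (2, 3), (3, 4)], 5)
        assert excl == {(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (2, 4)}
        assert p14 == {(0, 3), (1, 4)}

    def test_ring_pairs_use_shortest_path(self):
        # 5-ring: opposite atoms are 1-3 (excluded), nothing is 1-4
        ring = [(i, (i + 1) % 5) for i in range(5)]
        excl, p14 = enumerate_pairs(ring, 5)
        assert len(excl) == 10 and not p14

    def test_wrong_coordination_raises_structural_error(self, rh1):
        structure, _, _ = rh1
        bonds = [b for b in structure.bonds if b != (0, 1)]  # cut one Rh-ring bond
        with pytest.raises(r.StructureError):
            r.ComplexStructure(
                names=structure.names,
                elements=structure.elements,
                bonds=bonds,
                ligand_labels=structure.ligand_labels,
                oxidation_state="I",
            )


class TestSymmetryClasses:
    def test_cp_star_orbits(self, rh1):
        structure, _, _ = rh1
        classes = r.symmetry_classes(structure)
        sizes = sorted(len(c) for c in classes)
        by_size = {}
        for c in classes:
            by_size.setdefault(len(c), []).append(c)
        # five ring carbons, five methyl carbons in classes of 5;
        # fifteen methyl hydrogens together; both nitrogens paired
        assert sizes.count(5) == 2
        assert 15 in sizes
        assert sizes.count(1) == 1  # the metal is the only singleton in Rh(I)
        n_idx = [i for i, e in enumerate(structure.elements) if e == "N"]
        assert any(sorted(c) == sorted(n_idx) for c in classes)

    def test_bpy_carbons_pair_across_mirror_axis(self, rh1):
        structure, _, topo = rh1
        classes = r.symmetry_classes(structure)
        dii_c = [
            i
            for i, (e, lab) in enumerate(zip(structure.elements, structure.ligand_labels))
            if e == "C" and lab == "diimine"
        ]
        for c in classes:
            if set(c) & set(dii_c):
                assert len(c) == 2  # each bpy carbon pairs with its mirror image

    def test_halide_is_singleton(self, rh3):
        structure, _, _ = rh3
        classes = r.symmetry_classes(structure)
        cl = structure.elements.index("Cl")
        assert [cl] in classes


class TestChargeSymmetrization:
    def test_two_member_class_average(self):
        out = symmetrize_charges(ChargeSet(np.array([0.10, 0.14])), [[0, 1]])
        assert np.allclose(out.charges, [0.12, 0.12])

    def test_idempotence_and_total_preservation(self, rh1):
        structure, _, _ = rh1
        classes = r.symmetry_classes(structure)
        rng = np.random.default_rng(0)
        q = ChargeSet(rng.normal(0, 0.3, structure.n_atoms))
        once = symmetrize_charges(q, classes)
        twice = symmetrize_charges(once, classes)
        assert np.allclose(once.charges, twice.charges)
        assert once.total == pytest.approx(q.total, abs=1e-12)

    def test_out_of_range_class_raises(self):
        with pytest.raises(IndexError):
            symmetrize_charges(ChargeSet(np.array([0.1])), [[0, 5]])


class TestEquivalentTermAveraging:
    def test_metal_ring_bonds_averaged_to_group_mean(self, rh1):
        _, _, topo = rh1
        work = topo.copy()
        t = _types(work)
        vals = [2.10, 2.12, 2.14, 2.16, 2.18]
        k = 0
        for b in work.bonds:
            if {t[b.i], t[b.j]} == {"M1", "Y1"}:
                b.equilibrium = vals[k]
                k += 1
        out = average_equivalent_terms(work)
        eqs = [
            b.equilibrium
            for b in out.bonds
            if {t[b.i], t[b.j]} == {"M1", "Y1"}
        ]
        assert np.allclose(eqs, np.mean(vals))

    def test_averaging_is_a_fixed_point(self, rh1):
        _, _, topo = rh1
        once = average_equivalent_terms(topo)
        twice = average_equivalent_terms(once)
        for b1, b2 in zip(once.bonds, twice.bonds):
            assert b2.equilibrium == pytest.approx(b1.equilibrium, abs=1e-12)
            assert b2.force_constant == pytest.approx(b1.force_constant, abs=1e-12)
        for a1, a2 in zip(once.angles, twice.angles):
            assert a2.equilibrium == pytest.approx(a1.equilibrium, abs=1e-12)


class TestSymmetryInvariance:
    def _ring_permutation(self, rh1):
        """Atom permutation for a one-step (72 degree) Cp* ring rotation."""
        structure, _, topo = rh1
        perm = np.arange(topo.n_atoms)
        ring = [1, 2, 3, 4, 5]
        methyl = [6, 7, 8, 9, 10]
        for k in range(5):
            perm[ring[k]] = ring[(k + 1) % 5]
            perm[methyl[k]] = methyl[(k + 1) % 5]
            for h in range(3):
                perm[11 + 3 * k + h] = 11 + 3 * ((k + 1) % 5) + h
        return perm

    def test_energy_invariant_under_cyclic_ring_relabeling(self, rh1):
        _, coords, topo = rh1
        perm = self._ring_permutation(rh1)
        rng = np.random.default_rng(5)
        x = coords + rng.normal(0, 0.05, coords.shape)
        e0 = r.evaluate_energy(topo, x).total
        x_perm = np.empty_like(x)
        x_perm[perm] = x  # atom perm[i] takes the coordinates of atom i
        assert r.evaluate_energy(topo, x_perm).total == pytest.approx(e0, abs=1e-6)

    def test_energy_invariant_under_72_degree_ring_rotation(self, rh1):
        """Geometric rotation of the Cp* ligand about the metal-centroid
        axis maps the symmetrized complex onto itself."""
        _, coords, topo = rh1
        profile = r.run_scan(topo, coords, "ring-around", np.array([0.0, 72.0]))
        assert abs(profile.total[1] - profile.total[0]) < 1e-6
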