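"""Congener geometry, charges, enumeration and SDF round-trip."""

import itertools

import numpy as np
import pytest

from pbbqsar.congeners import (PBB_153, CongenerError, SubstitutionPattern,
                               assign_charges, build_congener,
                               congener_number, enumerate_congeners,
                               measure_dihedral, name_congener, read_sdf,
                               write_sdf)


class TestGeometry:
    def test_unsubstituted_biphenyl(self):
        mol = build_congener(SubstitutionPattern({}), dihedral=0.0)
        assert mol.n_atoms == 22
        assert mol.elements.count("C") == 12
        assert mol.elements.count("H") == 10
        # planar: all atoms in the xy-plane
        assert np.abs(mol.coords[:, 2]).max() < 1e-9

    def test_pbb153_composition(self):
        mol = build_congener(PBB_153)
        assert mol.congener_id == "PBB-153"
        assert mol.elements.count("Br") == 6
        assert mol.elements.count("H") == 4

    def test_ring_bond_lengths(self):
        mol = build_congener(PBB_153, dihedral=37.0)
        skel = mol.coords[mol.skeleton_indices()]
        for ring in (skel[:6], skel[6:]):
            for k in range(6):
                d = np.linalg.norm(ring[k] - ring[(k + 1) % 6])
                assert d == pytest.approx(1.39, abs=1e-6)
        # inter-ring bond
        assert np.linalg.norm(skel[0] - skel[6]) == pytest.approx(1.48, abs=1e-6)

    @pytest.mark.parametrize("dihedral", [0.0, 17.5, 44.0, 90.0])
    def test_dihedral_matches_request(self, dihedral):
        mol = build_congener(PBB_153, dihedral=dihedral)
        assert measure_dihedral(mol) == pytest.approx(dihedral, abs=1e-6)

    def test_deterministic_coordinates(self):
        a = build_congener(PBB_153, dihedral=44.0)
        b = build_congener(PBB_153, dihedral=44.0)
        assert np.array_equal(a.coords, b.coords)

    def test_bonded_distances_physical(self):
        pattern = SubstitutionPattern(
            {"2": "Br", "4": "Br", "5": "NO", "2'": "OCHO", "5'": "ONO",
             "4'": "OCN"})
        mol = build_congener(pattern)
        for i, j, _ in mol.bonds:
            d = np.linalg.norm(mol.coords[i] - mol.coords[j])
            assert 0.7 <= d <= 2.2

    def test_invalid_patterns_rejected(self):
        with pytest.raises(CongenerError):
            SubstitutionPattern({"1": "Br"})
        with pytest.raises(CongenerError):
            SubstitutionPattern({"3": "CF3"})
        with pytest.raises(ValueError):
            build_congener(PBB_153, dihedral=120.0)


class TestCharges:
    def test_neutrality(self):
        for pattern in (SubstitutionPattern({}), PBB_153,
                        SubstitutionPattern({"5": "NO", "5'": "OCN",
                                             "2": "Br"})):
            mol = assign_charges(build_congener(pattern))
            assert abs(mol.charges.sum()) < 1e-6

    def test_sign_pattern_matches_independent_peoe(self):
        """Charge signs agree with a from-scratch PEOE iteration."""
        mol = assign_charges(build_congener(PBB_153))
        ours = mol.charges
        theirs = _peoe_reference(mol)
        # compare where the reference is decisive (well away from zero)
        decisive = np.abs(theirs) > 1e-3
        assert decisive.sum() >= mol.n_atoms - 2
        assert np.all(np.sign(ours[decisive]) == np.sign(theirs[decisive]))

    def test_symmetry_equivalent_positions(self):
        # 2-bromo and 6-bromo are the same congener by ring-flip symmetry
        a = assign_charges(build_congener(
            SubstitutionPattern.from_bromines({"2"})))
        b = assign_charges(build_congener(
            SubstitutionPattern.from_bromines({"6"})))
        assert np.allclose(np.sort(a.charges), np.sort(b.charges), atol=1e-9)


def _peoe_reference(mol):
    """Minimal independent Gasteiger-Marsili PEOE for C/H/Br molecules."""
    params = {"C": (8.79, 9.32, 1.51), "H": (7.17, 6.24, -0.56),
              "Br": (10.08, 8.47, 2.16)}
    q = np.zeros(mol.n_atoms)
    chi_plus = {e: sum(params[e]) for e in params}
    chi_plus["H"] = 20.02
    for it in range(1, 7):
        chi = np.array([a + b * qi + c * qi * qi
                        for (a, b, c), qi in
                        (((params[e]), q[i]) for i, e in enumerate(mol.elements))])
        damp = 0.5 ** it
        dq = np.zeros_like(q)
        for i, j, _ in mol.bonds:
            if chi[j] > chi[i]:
                t = (chi[j] - chi[i]) / chi_plus[mol.elements[i]] * damp
                dq[i] += t
                dq[j] -= t
            elif chi[i] > chi[j]:
                t = (chi[i] - chi[j]) / chi_plus[mol.elements[j]] * damp
                dq[j] += t
                dq[i] -= t
        q += dq
    return q


class TestEnumeration:
    def test_homolog_counts(self):
        assert len(enumerate_congeners(10)) == 1
        assert len(enumerate_congeners(1)) == 3
        assert len(enumerate_congeners(range(1, 11))) == 209

    def test_matches_bruteforce_orbit_counting(self):
        """Counts per level equal orbit counting over all 2^10 patterns."""
        positions = [(r, p) for r in (0, 1) for p in (2, 3, 4, 5, 6)]

        def images(subset):
            out = set()
            for flip_a in (False, True):
                for flip_b in (False, True):
                    for swap in (False, True):
                        img = []
                        for r, p in subset:
                            pp = {2: 6, 6: 2, 3: 5, 5: 3}.get(p, p) \
                                if (flip_a, flip_b)[r] else p
                            rr = 1 - r if swap else r
                            img.append((rr, pp))
                        out.add(frozenset(img))
            return out

        orbits = {n: set() for n in range(1, 11)}
        for n in range(1, 11):
            for combo in itertools.combinations(positions, n):
                canon = min(images(frozenset(combo)), key=sorted)
                orbits[n].add(canon)
        for n in range(1, 11):
            assert len(enumerate_congeners(n)) == len(orbits[n])

    def test_ballschmiter_anchors(self):
        assert congener_number(PBB_153) == 153
        mono = enumerate_congeners(1)
        assert [name_congener(p) for p in mono] == ["PBB-1", "PBB-2", "PBB-3"]
        # PBB-2 is the 3-substituted monobromo congener
        assert mono[1].bromine_positions == frozenset({"3"})

    def test_derivative_names(self):
        assert name_congener(SubstitutionPattern(
            {"2": "Br", "4": "Br", "5": "NO", "2'": "Br", "4'": "Br",
             "5'": "OCN"})) == "5-NO-5'-OCN-PBB-153"
        assert name_congener(SubstitutionPattern(
            {"2": "Br", "4": "Br", "5": "NO", "2'": "Br", "4'": "Br",
             "5'": "NO"})) == "5,5'-NO-PBB-153"
        assert name_congener(SubstitutionPattern(
            {"2": "OCHO", "4": "Br", "5": "NO", "2'": "Br", "4'": "Br",
             "5'": "Br"})) == "2-OCHO-5-NO-PBB-153"


class TestSdfRoundTrip:
    def test_coordinates_and_labels_survive(self, tmp_path):
        mols = [assign_charges(build_congener(p))
                for p in (PBB_153, SubstitutionPattern({"3": "Br"}))]
        path = tmp_path / "ens.sdf"
        write_sdf(mols, path)
        back = read_sdf(path)
        assert [m.congener_id for m in back] == [m.congener_id for m in mols]
        for orig, rt in zip(mols, back):
            assert np.abs(orig.coords - rt.coords).max() < 1e-4
            assert rt.ring_labels == orig.ring_labels
            assert np.abs(orig.charges - rt.charges).max() < 1e-6

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.sdf"
        path.write_text("")
        with pytest.raises(CongenerError):
            read_sdf(path)
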