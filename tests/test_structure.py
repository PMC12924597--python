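"""PDB I/O, superposition, torsions, secondary structure and contacts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from citrullinome.structure import (
    Atom,
    Structure,
    assign_ss_from_torsions,
    backbone_torsions,
    compare_bfactors,
    compare_structures,
    dihedral,
    kabsch_superpose,
    per_residue_rmsd,
    polar_contacts,
    read_pdb,
    residue_pair_distance,
    ss_difference,
    write_pdb,
)
from citrullinome.synthetic_data import (
    add_polar_pseudo_atom,
    gen_ring_multimer,
    gen_toy_structure,
    perturb_structure,
)


def rigid(coords, angle_deg=37.0, axis="z", shift=(1.0, 2.0, 3.0)):
    th = math.radians(angle_deg)
    rz = np.array([[math.cos(th), -math.sin(th), 0],
                   [math.sin(th), math.cos(th), 0], [0, 0, 1]])
    return coords @ rz.T + np.asarray(shift)


class TestPdbIO:
    def test_round_trip_preserves_structure(self, helix12, tmp_path):
        write_pdb(helix12, tmp_path / "h.pdb")
        back = read_pdb(tmp_path / "h.pdb")
        assert len(back) == len(helix12)
        for a, b in zip(helix12.atoms, back.atoms):
            assert a.key == b.key and a.resname == b.resname
            assert np.allclose(a.xyz, b.xyz, atol=5e-4)  # 3-decimal columns
            assert abs(a.bfactor - b.bfactor) < 5e-3

    def test_multichain_and_cir_residue_preserved(self, helix12, tmp_path):
        ring = gen_ring_multimer(helix12, 3, radius=20.0)
        mod = perturb_structure(ring, site=6, magnitude=0.0, chain="B")
        write_pdb(mod, tmp_path / "r.pdb")
        back = read_pdb(tmp_path / "r.pdb")
        assert back.chains() == ["A", "B", "C"]
        assert back.residue_name("B", 6) == "CIR"
        assert len(back.residue_atoms("C", 1)) == len(helix12.residue_atoms("A", 1))

    def test_malformed_line_reports_line_number(self, tmp_path):
        (tmp_path / "bad.pdb").write_text("ATOM  garbage\n")
        with pytest.raises(ValueError, match="line 1"):
            read_pdb(tmp_path / "bad.pdb")

    def test_duplicate_atom_key_rejected(self):
        a = Atom(1, "CA", "ALA", "A", 1, 0, 0, 0)
        b = Atom(2, "CA", "ALA", "A", 1, 1, 1, 1)
        with pytest.raises(ValueError, match="duplicate"):
            Structure([a, b])

    def test_agrees_with_gemmi_reader(self, helix12, tmp_path):
        gemmi = pytest.importorskip("gemmi")
        write_pdb(helix12, tmp_path / "h.pdb")
        gst = gemmi.read_structure(str(tmp_path / "h.pdb"))
        gatoms = [(a.name, r.seqid.num, a.pos.x, a.pos.y, a.pos.z)
                  for model in gst for ch in model for r in ch for a in r]
        ours = read_pdb(tmp_path / "h.pdb")
        assert len(gatoms) == len(ours)
        for (name, seq, x, y, z), a in zip(gatoms, ours.atoms):
            assert (name, seq) == (a.name, a.resseq)
            assert np.allclose([x, y, z], a.xyz, atol=1e-6)


class TestKabsch:
    def test_recovers_rigid_transform(self, helix12):
        mob = helix12.with_coords(rigid(helix12.coords()))
        sup = kabsch_superpose(mob, helix12)
        assert sup.global_rmsd <= 1e-9
        assert np.allclose(sup.transformed.coords(), helix12.coords(), atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_invariant_under_rigid_pretransform(self, helix12):
        mod = perturb_structure(helix12, site=6, magnitude=1.5, seed=1)
        base = kabsch_superpose(mod, helix12).global_rmsd
        pre = mod.with_coords(rigid(mod.coords(), angle_deg=113.0, shift=(-4, 9, 2)))
        assert kabsch_superpose(pre, helix12).global_rmsd == pytest.approx(base, abs=1e-9)

    def test_reflection_forbidden_on_mirror_image(self, helix12):
        mirrored = helix12.with_coords(helix12.coords() * np.array([1.0, 1.0, -1.0]))
        sup = kabsch_superpose(mirrored, helix12)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.global_rmsd > 0.1  # a reflection would fit exactly

    def test_errors_on_degenerate_selections(self):
        def line(n):
            return Structure([Atom(i + 1, "CA", "ALA", "A", i + 1, float(i), 0, 0)
                              for i in range(n)])
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(line(2), line(2))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line(5), line(5))


class TestPerResidueRmsd:
    def test_identical_structures_zero(self, helix12):
        tab = per_residue_rmsd(helix12, helix12)
        assert np.allclose(tab["rmsd"], 0.0)

    def test_single_displaced_ca(self, helix12):
        moved = helix12.copy()
        for a in moved.atoms:
            if a.resseq == 5 and a.name == "CA":
                a.x += 2.0
        tab = per_residue_rmsd(moved, helix12).set_index("resseq")
        assert tab.loc[5, "rmsd"] == pytest.approx(2.0)
        assert np.allclose(tab.drop(index=5)["rmsd"], 0.0)

    def test_global_rmsd_is_atom_weighted_rms_of_per_residue(self, helix12):
        mod = perturb_structure(helix12, site=6, magnitude=2.0, seed=2)
        sup = kabsch_superpose(mod, helix12)
        tab = per_residue_rmsd(sup.transformed, helix12)
        pooled = math.sqrt((tab["n_atoms"] * tab["rmsd"] ** 2).sum()
                           / tab["n_atoms"].sum())
        assert pooled == pytest.approx(sup.global_rmsd, abs=1e-12)


class TestBfactors:
    def test_identity_and_constant_offset(self, helix12):
        assert np.allclose(compare_bfactors(helix12, helix12)["delta"], 0.0)
        shifted = helix12.copy()
        for a in shifted.atoms:
            a.bfactor += 5.0
        tab = compare_bfactors(helix12, shifted)
        assert np.allclose(tab["delta"], -5.0)

    def test_hand_set_three_residue_case(self):
        def s(bs):
            return Structure([Atom(i + 1, "CA", "ALA", "A", i + 1, float(i), 0, 0,
                                   bfactor=b) for i, b in enumerate(bs)])
        tab = compare_bfactors(s([10, 20, 30]), s([5, 25, 30]))
        assert tab["delta"].tolist() == [5.0, -5.0, 0.0]


class TestTorsions:
    def test_constructed_dihedral(self):
        p = [np.array(v, dtype=float) for v in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
        assert dihedral(*p) == pytest.approx(180.0)

    def test_build_recompute_round_trip(self):
        s = gen_toy_structure("helix", 10)
        t = backbone_torsions(s)
        assert np.allclose(t["phi"].iloc[1:], -57.0, atol=1e-6)
        assert np.allclose(t["psi"].iloc[:-1], -47.0, atol=1e-6)

    def test_termini_undefined(self, strand8):
        t = backbone_torsions(strand8)
        assert math.isnan(t["phi"].iloc[0]) and math.isnan(t["psi"].iloc[-1])
        assert t["phi"].iloc[1:].notna().all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.floats(min_value=-179.0, max_value=179.0),
                              st.floats(min_value=-179.0, max_value=179.0)),
                    min_size=4, max_size=10))
    def test_arbitrary_angle_round_trip(self, angles):
        from citrullinome import synthetic_data as sd
        orig = sd._phi_psi_for
        sd_angles = list(angles)
        try:
            sd._phi_psi_for = lambda kind, n: sd_angles
            s = gen_toy_structure("helix", len(sd_angles), with_cb=False)
        finally:
            sd._phi_psi_for = orig
        t = backbone_torsions(s)
        for i in range(1, len(sd_angles)):
            assert t["phi"].iloc[i] == pytest.approx(sd_angles[i][0], abs=1e-6)
        for i in range(len(sd_angles) - 1):
            assert t["psi"].iloc[i] == pytest.approx(sd_angles[i][1], abs=1e-6)


class TestSecondaryStructure:
    def test_ideal_helix_and_strand(self, helix12, strand8):
        ss_h = assign_ss_from_torsions(backbone_torsions(helix12))["ss"]
        assert "".join(ss_h) == "C" + "H" * 10 + "C"
        ss_e = assign_ss_from_torsions(backbone_torsions(strand8))["ss"]
        assert "".join(ss_e) == "C" + "E" * 6 + "C"

    def test_alternating_angles_demoted_to_coil(self):
        from citrullinome import synthetic_data as sd
        angles = [(-57.0, -47.0), (-120.0, 130.0)] * 5
        orig = sd._phi_psi_for
        try:
            sd._phi_psi_for = lambda kind, n: angles
            s = gen_toy_structure("helix", 10, with_cb=False)
        finally:
            sd._phi_psi_for = orig
        ss = assign_ss_from_torsions(backbone_torsions(s))["ss"]
        assert set(ss) == {"C"}

    def test_invariant_under_rigid_motion(self, helix12):
        moved = helix12.with_coords(rigid(helix12.coords(), 71.0, shift=(5, -2, 8)))
        a = assign_ss_from_torsions(backbone_torsions(helix12))
        b = assign_ss_from_torsions(backbone_torsions(moved))
        assert a["ss"].tolist() == b["ss"].tolist()

    def test_ss_difference_counts(self, helix12):
        a = assign_ss_from_torsions(backbone_torsions(helix12))
        tab, counts = ss_difference(a, a)
        assert not tab["changed"].any() and not counts
        b = a.copy()
        b.loc[5, "ss"] = "E"
        tab, counts = ss_difference(a, b)
        assert tab["changed"].sum() == 1
        assert counts == {f"{a.loc[5, 'ss']}->E": 1}
        assert sum(counts.values()) == tab["changed"].sum()


class TestContacts:
    def _two_chain(self, d):
        atoms = [
            Atom(1, "N", "GLY", "A", 1, 0, 0, 0),
            Atom(2, "CA", "GLY", "A", 1, 1.5, 0, 0),
            Atom(3, "C", "GLY", "A", 1, 2.0, 1.4, 0),
            Atom(4, "OE1", "GLU", "A", 2, 5.0, 0, 0),
            Atom(5, "CA", "GLU", "A", 2, 6.0, 1.0, 0),
            Atom(6, "NH1", "CIR", "B", 1, 5.0 + d, 0, 0),
            Atom(7, "CA", "CIR", "B", 1, 6.0 + d, -1.0, 0),
        ]
        return Structure(atoms)

    def test_engineered_inter_chain_pair_found(self):
        s = self._two_chain(2.9)
        contacts = polar_contacts(s, cutoff=3.5, scope="inter")
        assert len(contacts) == 1
        c = contacts[0]
        assert {(c.chain_a, c.atom_a), (c.chain_b, c.atom_b)} == \
            {("A", "OE1"), ("B", "NH1")}
        assert c.distance == pytest.approx(2.9)

    def test_cutoff_boundary_excludes(self):
        assert polar_contacts(self._two_chain(3.6), cutoff=3.5, scope="inter") == []

    def test_symmetric_under_chain_relabel(self):
        s = self._two_chain(2.9)
        swapped = Structure([
            Atom(a.serial, a.name, a.resname, {"A": "B", "B": "A"}[a.chain],
                 a.resseq, a.x, a.y, a.z) for a in s.atoms])
        c1 = polar_contacts(s, cutoff=3.5, scope="inter")
        c2 = polar_contacts(swapped, cutoff=3.5, scope="inter")
        assert len(c1) == len(c2) == 1
        assert c1[0].distance == pytest.approx(c2[0].distance)

    def test_distance_matches_residue_pair_distance(self):
        s = self._two_chain(2.9)
        c = polar_contacts(s, cutoff=3.5, scope="inter")[0]
        d = residue_pair_distance(s, (c.chain_a, c.resseq_a, c.atom_a),
                                  (c.chain_b, c.resseq_b, c.atom_b))
        assert d == pytest.approx(c.distance)

    def test_point_distances(self):
        s = Structure([Atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
                       Atom(2, "CA", "ALA", "A", 2, 3, 4, 0)])
        assert residue_pair_distance(s, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0
        assert residue_pair_distance(s, ("A", 1, "CA"), ("A", 2, "CA")) == 5.0
        with pytest.raises(KeyError):
            residue_pair_distance(s, ("A", 1, "CB"), ("A", 2, "CA"))


class TestCompareStructures:
    def test_exact_copy_reports_no_differences(self, helix12):
        rep = compare_structures(helix12, helix12.copy(), site=6)
        assert rep.global_rmsd <= 1e-12
        assert np.allclose(rep.per_residue["rmsd"], 0.0)
        assert not rep.ss_changes
        assert rep.contacts_gained == [] and rep.contacts_lost == []

    def test_perturbation_localizes_to_site_window(self):
        native = gen_toy_structure("mixed", 30, seed=9)
        mod = perturb_structure(native, site=15, magnitude=2.0, window=3, seed=9)
        rep = compare_structures(native, mod, site=15)
        tab = rep.per_residue.set_index("resseq")
        assert tab["rmsd"].idxmax() in range(12, 19)
        assert tab.loc[15, "near_site"]
        # fitting only the unmoved residues isolates the perturbation exactly
        unmoved = {("A", r) for r in range(1, 31) if abs(r - 15) > 4}
        sup = kabsch_superpose(mod, native, residues=unmoved)
        t2 = per_residue_rmsd(sup.transformed, native).set_index("resseq")
        outside = [r for r in range(1, 31) if abs(r - 15) > 4]
        assert (t2.loc[outside, "rmsd"] <= 1e-6).all()
        assert t2["rmsd"].idxmax() == 15

    def test_renamed_site_residue_round_trips(self, helix12, tmp_path):
        mod = perturb_structure(helix12, site=6, magnitude=0.0)
        assert mod.residue_name("A", 6) == "CIR"
        unchanged = [a for a in mod.atoms if a.resseq != 6]
        orig = [a for a in helix12.atoms if a.resseq != 6]
        assert all(np.array_equal(a.xyz, b.xyz) for a, b in zip(unchanged, orig))
        write_pdb(mod, tmp_path / "m.pdb")
        assert read_pdb(tmp_path / "m.pdb").residue_name("A", 6) == "CIR"


class TestRingMultimer:
    def test_rigid_copies_preserve_intra_chain_geometry(self, helix12):
        ring = gen_ring_multimer(helix12, 2, radius=30.0)
        ca_a = np.array([a.xyz for a in ring.atoms if a.chain == "A" and a.name == "CA"])
        ca_b = np.array([a.xyz for a in ring.atoms if a.chain == "B" and a.name == "CA"])
        da = np.linalg.norm(ca_a[:, None] - ca_a[None], axis=-1)
        db = np.linalg.norm(ca_b[:, None] - ca_b[None], axis=-1)
        assert np.allclose(da, db, atol=1e-9)

    def test_twelve_chains_round_trip(self, helix12, tmp_path):
        ring = gen_ring_multimer(helix12, 12, radius=25.0)
        write_pdb(ring, tmp_path / "ring.pdb")
        assert read_pdb(tmp_path / "ring.pdb").chains() == list("ABCDEFGHIJKL")

    def test_copy_count_bounds(self, helix12):
        with pytest.raises(ValueError):
            gen_ring_multimer(helix12, 1, radius=10.0)
        with pytest.raises(ValueError):
            gen_ring_multimer(helix12, 27, radius=10.0)

    def test_engineered_new_interchain_bond_is_the_only_gained_contact(self, helix12):
        ring = gen_ring_multimer(helix12, 6, radius=28.0)
        assert polar_contacts(ring, cutoff=3.5, scope="inter") == []
        n_b = ring.get_atom("B", 1, "N")
        ca_a = ring.get_atom("A", 12, "CA")
        u = (ca_a.xyz - n_b.xyz) / np.linalg.norm(ca_a.xyz - n_b.xyz)
        mod = add_polar_pseudo_atom(ring, "A", 12, "OX1", n_b.xyz + 2.9 * u)
        rep = compare_structures(ring, mod, contact_scope="inter")
        assert len(rep.contacts_gained) == 1 and rep.contacts_lost == []
        g = rep.contacts_gained[0]
        assert {(g.chain_a, g.resseq_a, g.atom_a), (g.chain_b, g.resseq_b, g.atom_b)} \
            == {("A", 12, "OX1"), ("B", 1, "N")}
        assert g.distance == pytest.approx(2.9, abs=1e-6)
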