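"""Nucleotide building: stripping, sugar templates, base attachment,
chi expansion, backrub and candidate enumeration."""

import itertools

import numpy as np
import pytest

from nucpack import synth
from nucpack.build import (
    MAINCHAIN_ATOMS,
    BuildConfig,
    attach_base,
    backrub,
    enumerate_candidates,
    expand_chi,
    place_sugar,
    strip_to_mainchain,
    sugar_conformers_for,
)
from nucpack.geom import (
    PuckerClass,
    chi_angle,
    circular_difference,
    pucker_state,
    rotation_about_axis,
)


@pytest.fixture(scope="module")
def ideal_dg():
    return synth.ideal_nucleotide("dG", 162.0, 37.0, 250.0)


class TestStrip:
    def test_complete_residue_keeps_eight(self, ideal_dg):
        stripped = strip_to_mainchain(ideal_dg)
        assert set(stripped.atoms) == MAINCHAIN_ATOMS
        assert len(stripped.atoms) == 8

    def test_idempotent(self, ideal_dg):
        once = strip_to_mainchain(ideal_dg)
        twice = strip_to_mainchain(once)
        assert set(twice.atoms) == set(once.atoms)
        for n in once.atoms:
            assert np.allclose(once.atoms[n].position, twice.atoms[n].position)

    def test_terminal_residue_keeps_five(self, ideal_dg):
        res = ideal_dg.copy()
        for n in ("P", "OP1", "OP2"):
            del res.atoms[n]
        stripped = strip_to_mainchain(res)
        assert len(stripped.atoms) == 5


class TestSugarTemplates:
    def test_counts_per_class(self):
        assert len(sugar_conformers_for(PuckerClass.ENDO3)) == 3
        assert len(sugar_conformers_for(PuckerClass.ENDO2)) == 4

    def test_canonical_phases(self):
        by_name = {t.name: t for t in sugar_conformers_for(PuckerClass.ENDO3)}
        assert by_name["3E"].canonical_P == 18.0
        by_name2 = {t.name: t for t in sugar_conformers_for(PuckerClass.ENDO2)}
        assert by_name2["2E"].canonical_P == 162.0
        assert by_name2["2T1"].canonical_P == 144.0

    def test_template_measured_phase_close_to_canonical(self):
        for cls in PuckerClass:
            for t in sugar_conformers_for(cls, "ribose"):
                measured = pucker_state(t.residue).P
                assert circular_difference(measured, t.canonical_P) <= 2.0


class TestPlaceSugar:
    def test_self_consistency_on_matching_pucker(self):
        nt = synth.ideal_nucleotide("A", 18.0, 40.0, 200.0)
        mainchain = strip_to_mainchain(nt)
        template = next(
            t for t in sugar_conformers_for(PuckerClass.ENDO3, "ribose") if t.name == "3E"
        )
        placed = place_sugar(template, mainchain)
        anchors = ("C3'", "C4'", "C5'")
        fit = np.sqrt(
            np.mean(np.sum((placed.coords(anchors) - nt.coords(anchors)) ** 2, axis=1))
        )
        assert fit <= 0.05

    def test_equivariance_under_rigid_transform(self, ideal_dg):
        mainchain = strip_to_mainchain(ideal_dg)
        template = sugar_conformers_for(PuckerClass.ENDO2)[0]
        placed = place_sugar(template, mainchain)
        rot = rotation_about_axis([1.0, 1.0, 0.0], 35.0)
        shift = np.array([2.0, -1.0, 4.0])
        placed_moved = place_sugar(template, mainchain.transform(rot, shift))
        for name, atom in placed.atoms.items():
            expected = rot @ atom.position + shift
            assert np.allclose(placed_moved.atoms[name].position, expected, atol=1e-8)

    def test_endo2_gives_four_distinct_phases(self, ideal_dg):
        mainchain = strip_to_mainchain(ideal_dg)
        phases = []
        for t in sugar_conformers_for(PuckerClass.ENDO2):
            placed = place_sugar(t, mainchain)
            phases.append(round(pucker_state(placed).P))
        assert len(set(phases)) == 4

    def test_placed_phase_tracks_template(self, ideal_dg):
        mainchain = strip_to_mainchain(ideal_dg)
        for t in sugar_conformers_for(PuckerClass.ENDO2):
            placed = place_sugar(t, mainchain)
            assert circular_difference(pucker_state(placed).P, t.canonical_P) <= 5.0


class TestAttachBase:
    def test_chi_round_trip(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[1], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dA", 250.0)
        assert chi_angle(cand.residue) == pytest.approx(250.0, abs=0.01)

    def test_purine_vs_pyrimidine_frames(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        pur = attach_base(sugar, "dG", 210.0).residue
        pyr = attach_base(sugar, "dC", 210.0).residue
        assert "N9" in pur.atoms and "C8" in pur.atoms
        assert "N9" not in pyr.atoms and "N1" in pyr.atoms
        assert chi_angle(pur) == pytest.approx(210.0, abs=0.01)
        assert chi_angle(pyr) == pytest.approx(210.0, abs=0.01)

    def test_sugar_identical_across_chi(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        c1 = attach_base(sugar, "dA", 200.0).residue
        c2 = attach_base(sugar, "dA", 250.0).residue
        for n in ("C1'", "C2'", "O4'", "C3'", "C4'"):
            assert np.allclose(c1.atoms[n].position, c2.atoms[n].position)

    def test_unknown_nucleoside_raises(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        with pytest.raises(ValueError):
            attach_base(sugar, "dX", 200.0)


class TestExpandChi:
    def test_three_increments(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dG", 240.0)
        out = expand_chi(cand, (-7.0, 0.0, 7.0))
        assert len(out) == 3
        for c in out:
            assert chi_angle(c.residue) == pytest.approx(
                (240.0 + c.dchi) % 360.0, abs=0.01
            )

    def test_identity_increment_is_copy(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dG", 240.0)
        (out,) = expand_chi(cand, (0.0,))
        for n, a in cand.residue.atoms.items():
            assert np.allclose(out.residue.atoms[n].position, a.position)

    def test_rigid_rotation_preserves_axis_distances(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dA", 200.0)
        rotated = expand_chi(cand, (0.0, 7.0))[1]
        c1 = cand.residue.atoms["C1'"].position
        n9 = cand.residue.atoms["N9"].position
        axis = (n9 - c1) / np.linalg.norm(n9 - c1)

        def axis_distance(p):
            v = p - c1
            return np.linalg.norm(v - np.dot(v, axis) * axis)

        for n in ("C4", "C8", "N3", "C6"):
            assert axis_distance(rotated.residue.atoms[n].position) == pytest.approx(
                axis_distance(cand.residue.atoms[n].position), abs=1e-9
            )


class TestBackrub:
    def test_zero_angle_identity(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dG", 250.0)
        out = backrub(cand, 0.0)
        for n, a in cand.residue.atoms.items():
            assert np.allclose(out.residue.atoms[n].position, a.position)

    def test_axis_atoms_invariant(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dG", 250.0)
        out = backrub(cand, 7.0)
        for n in ("C3'", "C4'"):
            assert np.allclose(
                out.residue.atoms[n].position, cand.residue.atoms[n].position, atol=1e-9
            )

    def test_composition_is_identity(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dG", 250.0)
        out = backrub(backrub(cand, 7.0), -7.0)
        for n, a in cand.residue.atoms.items():
            assert np.allclose(out.residue.atoms[n].position, a.position, atol=1e-9)

    def test_pp_axis_requires_next_phosphate(self, ideal_dg):
        sugar = place_sugar(
            sugar_conformers_for(PuckerClass.ENDO2)[0], strip_to_mainchain(ideal_dg)
        )
        cand = attach_base(sugar, "dG", 250.0)
        with pytest.raises(Exception):
            backrub(cand, 7.0, axis="PP")
        out = backrub(cand, 7.0, axis="PP", next_p_position=np.array([10.0, 0.0, 0.0]))
        assert np.allclose(
            out.residue.atoms["P"].position, cand.residue.atoms["P"].position, atol=1e-9
        )


class TestEnumerate:
    def test_count_law_on_config_grid(self, example_library, duplex_b):
        res3 = synth.ideal_nucleotide("A", 18.0, 40.0, 200.0)  # ENDO3 ribo
        res2 = duplex_b.get("A", 1)  # ENDO2 deoxy
        for res, n_sugar in ((res3, 3), (res2, 4)):
            for dchi, br, h in itertools.product(
                ((0.0,), (-7.0, 0.0, 7.0)), ((0.0,), (-7.0, 0.0, 7.0)), (1, 3)
            ):
                cfg = BuildConfig(dchi=dchi, backrub_angles=br, h_placements=h)
                cands = enumerate_candidates(res, example_library, cfg)
                n_rot = len(example_library.group(
                    res.name, pucker_state(res).pucker_class.name
                ))
                assert len(cands) == n_rot * n_sugar * h * len(dchi) * len(br)

    def test_example_counts(self, example_library):
        # 3'-endo-like position with 2 rotamers, both expansions on:
        # 2 x 3 x 1 x 3 x 3 = 54
        res = synth.ideal_nucleotide("U", 18.0, 40.0, 200.0)
        cfg = BuildConfig(dchi=(-7.0, 0.0, 7.0), backrub_angles=(-7.0, 0.0, 7.0))
        assert len(enumerate_candidates(res, example_library, cfg)) == 54
        # expansions off, 2'-endo-like with 3 rotamers: 3 x 4 = 12
        res2 = synth.ideal_nucleotide("dG", 162.0, 37.0, 250.0)
        assert len(enumerate_candidates(res2, example_library, BuildConfig())) == 12

    def test_allowed_nucleosides_sum(self, example_library, duplex_b):
        res = duplex_b.get("A", 2)
        cfg = BuildConfig(allowed_nucleosides=("dA", "dT", "dG", "dC"))
        cands = enumerate_candidates(res, example_library, cfg)
        expected = sum(
            len(example_library.group(n, "ENDO2")) * 4 for n in ("dA", "dT", "dG", "dC")
        )
        assert len(cands) == expected

    def test_candidate_chi_matches_provenance(self, example_library, duplex_b):
        res = duplex_b.get("A", 1)
        cfg = BuildConfig(dchi=(-7.0, 0.0, 7.0))
        for cand in enumerate_candidates(res, example_library, cfg):
            assert (
                circular_difference(chi_angle(cand.residue), cand.chi_target) <= 0.5
            )

    def test_closest_rotamer_recovery(self, example_library, duplex_b):
        # reference chi coincides with a library entry: some candidate
        # must match it exactly (delta chi = 0)
        res = duplex_b.get("A", 3)
        cands = enumerate_candidates(res, example_library, BuildConfig())
        deltas = [
            circular_difference(chi_angle(c.residue), chi_angle(res)) for c in cands
        ]
        assert min(deltas) == pytest.approx(0.0, abs=1e-6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BuildConfig(dchi=(-7.0, 7.0))
        with pytest.raises(ValueError):
            BuildConfig(backrub_angles=(5.0,))
        with pytest.raises(ValueError):
            BuildConfig(h_placements=0)
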