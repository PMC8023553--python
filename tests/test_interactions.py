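import numpy as np
import pytest
from helpers import brute_force_interchain_pairs, random_rotation, transform_dimer

from dimerfeat import (
    FixtureSpec, InteractionThresholds, build_fixture, build_random_dimer,
    close_contacts, detect_all, fingerprint, hydrogen_bonds,
    hydrophobic_contacts, pi_systems, salt_bridges,
)
from dimerfeat.interactions import KINDS, fit_ring


def _kinds(dimer, **thr):
    return {r.kind for r in detect_all(dimer, InteractionThresholds(**thr))}


class TestCloseContacts:
    def test_single_pair_within_both_cutoffs(self):
        dimer = build_fixture(FixtureSpec("hydrophobic_pair", {"distance": 2.4}))
        c25 = close_contacts(dimer, 2.5)
        c40 = close_contacts(dimer, 4.0)
        key_a, key_b = dimer.chain_a[0].key, dimer.chain_b[0].key
        assert c25[key_a] == c25[key_b] == 1
        assert c40[key_a] >= 1

    def test_pair_at_3A_counts_only_at_4A(self):
        dimer = build_fixture(FixtureSpec("hbond_pair", {"d_DA": 3.0}))
        assert sum(close_contacts(dimer, 2.5).values()) == 0
        assert close_contacts(dimer, 4.0)[dimer.chain_a[0].key] >= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_kdtree_equals_brute_force_and_oracle(self, seed):
        dimer = build_random_dimer(12, separation=4.0, seed=seed)
        for cutoff in (2.5, 4.0):
            kd = close_contacts(dimer, cutoff, method="kdtree")
            brute = close_contacts(dimer, cutoff, method="brute")
            oracle = brute_force_interchain_pairs(dimer, cutoff)
            assert kd == brute == oracle

    def test_short_cutoff_counts_never_exceed_long(self):
        dimer = build_random_dimer(15, separation=3.5, seed=9)
        c25, c40 = close_contacts(dimer, 2.5), close_contacts(dimer, 4.0)
        assert all(c25[k] <= c40[k] for k in c25)


class TestHydrophobic:
    def test_apolar_pair_detected(self):
        dimer = build_fixture(FixtureSpec("hydrophobic_pair", {"distance": 3.8}))
        recs = hydrophobic_contacts(dimer)
        assert any(r.atom_a == "CD1" and r.atom_b == "CG1" for r in recs)

    def test_polar_atom_not_counted(self):
        # LEU CD1 vs SER OG at 3.0 Å: oxygen is not an apolar carbon
        dimer = build_fixture(FixtureSpec("hbond_pair", {"d_DA": 3.0}))
        assert hydrophobic_contacts(dimer) == []

    def test_beyond_cutoff_rejected(self):
        dimer = build_fixture(FixtureSpec("hydrophobic_pair", {"distance": 4.5}))
        assert all(r.distance <= 4.0 for r in hydrophobic_contacts(dimer))
        assert not any(r.atom_a == "CD1" and r.atom_b == "CG1"
                       for r in hydrophobic_contacts(dimer))

    def test_chain_swap_symmetry(self):
        dimer = build_fixture(FixtureSpec("hydrophobic_pair", {"distance": 3.8}))
        assert len(hydrophobic_contacts(dimer)) == len(hydrophobic_contacts(dimer.swapped()))


class TestHydrogenBonds:
    def test_linear_geometry_detected(self):
        dimer = build_fixture(FixtureSpec("hbond_pair", {"d_DA": 2.9, "angle": 180.0}))
        recs = hydrogen_bonds(dimer)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.9, abs=1e-6)
        assert recs[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_bent_geometry_rejected(self):
        dimer = build_fixture(FixtureSpec("hbond_pair", {"d_DA": 2.9, "angle": 120.0}))
        assert hydrogen_bonds(dimer) == []  # 60° deviation > 40°

    def test_long_distance_rejected(self):
        dimer = build_fixture(FixtureSpec("hbond_pair", {"d_DA": 4.5}))
        assert hydrogen_bonds(dimer) == []

    def test_without_hydrogen_distance_only_with_flag(self):
        dimer = build_fixture(FixtureSpec("hbond_pair", {"d_DA": 2.9, "angle": 120.0}))
        for res in dimer.residues():
            res.atoms = [a for a in res.atoms if not a.is_hydrogen]
        recs = hydrogen_bonds(dimer)
        assert len(recs) == 1
        assert "no_hydrogen" in recs[0].flags


class TestSaltBridges:
    def test_guanidinium_carboxylate_detected(self):
        dimer = build_fixture(FixtureSpec("salt_bridge_pair", {"distance": 4.0}))
        recs = salt_bridges(dimer)
        assert len(recs) == 1
        assert {recs[0].resn_a, recs[0].resn_b} == {"ARG", "GLU"}
        assert recs[0].distance == pytest.approx(4.0, abs=1e-6)

    def test_beyond_cutoff_rejected(self):
        dimer = build_fixture(FixtureSpec("salt_bridge_pair", {"distance": 6.5}))
        assert salt_bridges(dimer) == []

    def test_porin_like_glu_arg_geometry_detected(self):
        # Guanidinium-to-carboxylate arrangement at a typical observed
        # closest-atom separation (~2.8 Å, as in bacterial porin interfaces)
        dimer = build_fixture(FixtureSpec("salt_bridge_pair", {"distance": 2.8}))
        recs = salt_bridges(dimer)
        assert len(recs) == 1 and recs[0].kind == "salt_bridge"


class TestPiSystems:
    def test_parallel_rings_are_pi_pi(self):
        dimer = build_fixture(FixtureSpec("parallel_rings",
                                          {"centroid_dist": 3.6, "dihedral": 0.0}))
        kinds = [r.kind for r in pi_systems(dimer)]
        assert kinds == ["pi_pi"]

    def test_perpendicular_rings_are_t_stack(self):
        dimer = build_fixture(FixtureSpec("t_rings",
                                          {"centroid_dist": 5.0, "dihedral": 90.0}))
        kinds = [r.kind for r in pi_systems(dimer)]
        assert kinds == ["t_stack"]

    def test_intermediate_angle_is_neither(self):
        dimer = build_fixture(FixtureSpec("parallel_rings",
                                          {"centroid_dist": 3.6, "dihedral": 50.0}))
        assert pi_systems(dimer) == []

    def test_far_t_rings_rejected(self):
        dimer = build_fixture(FixtureSpec("t_rings",
                                          {"centroid_dist": 6.0, "dihedral": 90.0}))
        assert pi_systems(dimer) == []

    def test_cation_over_ring_detected(self):
        dimer = build_fixture(FixtureSpec("cation_ring", {"height": 4.0}))
        kinds = [r.kind for r in pi_systems(dimer)]
        assert kinds == ["cation_pi"]

    def test_distant_cation_rejected(self):
        dimer = build_fixture(FixtureSpec("cation_ring", {"height": 7.0}))
        assert pi_systems(dimer) == []

    def test_pi_pi_takes_precedence_per_pair(self):
        # close parallel rings satisfy both stacking geometries' distance
        # bounds; the pair must be assigned only pi_pi
        dimer = build_fixture(FixtureSpec("parallel_rings",
                                          {"centroid_dist": 3.6, "dihedral": 0.0}))
        kinds = [r.kind for r in pi_systems(dimer)]
        assert kinds.count("pi_pi") == 1 and "t_stack" not in kinds

    def test_incomplete_ring_skipped_with_warning(self, caplog):
        dimer = build_fixture(FixtureSpec("parallel_rings", {}))
        dimer.chain_a[0].atoms = [a for a in dimer.chain_a[0].atoms if a.name != "CZ"]
        with caplog.at_level("WARNING", logger="dimerfeat"):
            assert pi_systems(dimer) == []
        assert "ring" in caplog.text


class TestInvariances:
    @pytest.mark.parametrize("seed", range(6))
    def test_rigid_motion_and_chain_swap(self, seed):
        dimer = build_random_dimer(10, separation=4.5, seed=seed)
        base = fingerprint(dimer)
        cols = list(KINDS)

        rot, trans = random_rotation(seed + 100)
        moved = fingerprint(transform_dimer(dimer, rot, trans))
        assert (base[cols].to_numpy() == moved[cols].to_numpy()).all()

        swapped = fingerprint(dimer.swapped())
        merged = base.merge(swapped, on=["chain", "resi", "icode"], suffixes=("", "_s"))
        for c in cols:
            assert (merged[c] == merged[f"{c}_s"]).all()

    def test_records_satisfy_their_own_thresholds(self):
        th = InteractionThresholds()
        for seed in range(4):
            dimer = build_random_dimer(12, separation=4.0, seed=seed + 50)
            for rec in detect_all(dimer, th):
                limit = {"hydrophobic": th.hydrophobic, "hbond": th.hbond_dist,
                         "salt_bridge": th.salt_bridge, "pi_pi": th.pi_pi_dist,
                         "t_stack": th.t_stack_dist, "cation_pi": th.cation_pi_dist}[rec.kind]
                assert rec.distance <= limit
                if rec.kind == "pi_pi":
                    assert rec.angle <= th.pi_pi_angle
                if rec.kind == "t_stack":
                    assert abs(rec.angle - 90.0) <= th.t_stack_angle_dev
                if rec.kind == "hbond" and rec.angle is not None:
                    assert rec.angle <= th.hbond_angle_dev


class TestFingerprint:
    def test_separated_dimer_all_zero(self, separated_dimer):
        fp = fingerprint(separated_dimer)
        assert (fp[list(KINDS)].to_numpy() == 0).all()

    def test_salt_bridge_fixture_marks_exactly_the_partner_residues(self):
        dimer = build_fixture(FixtureSpec("salt_bridge_pair", {"distance": 4.0}))
        fp = fingerprint(dimer)
        assert fp["salt_bridge"].tolist() == [1, 1]

    def test_ring_fit_properties(self):
        dimer = build_fixture(FixtureSpec("parallel_rings", {}))
        ring = fit_ring(dimer.chain_a[0], ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"])
        assert np.linalg.norm(ring.normal) == pytest.approx(1.0, abs=1e-9)
        assert ring.rms_residual < 0.25
        assert ring.radius == pytest.approx(1.39, abs=1e-6)
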