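import numpy as np
import pytest
from scipy.optimize import brentq

from mbrot import model_builder as mb
from mbrot import toy_systems
from mbrot.structio import MolecularStructure


def lj(r, sigma):
    return (sigma / r) ** 12 - 2 * (sigma / r) ** 6


class TestIsoenergeticSolve:
    def test_degenerate_limit(self):
        sigma, frac = mb.solve_isoenergetic_sigma(1.0, 1.0)
        assert sigma == pytest.approx(1.0)
        assert frac == pytest.approx(1.0)

    @pytest.mark.parametrize("r_a,r_b", [(1.0, 1.2), (1.0, 2.0), (0.4, 0.55), (0.3, 0.32)])
    def test_closed_form_matches_root_finding(self, r_a, r_b):
        """The closed-form well position makes both endpoint distances
        isoenergetic; cross-checked with a 1D numeric root solve."""
        sigma, frac = mb.solve_isoenergetic_sigma(r_a, r_b)
        assert lj(r_a, sigma) == pytest.approx(lj(r_b, sigma), abs=1e-12)
        # independent numeric oracle on g(sigma) = V(r_a) - V(r_b)
        g = lambda s: lj(r_a, s) - lj(r_b, s)  # noqa: E731
        sigma_oracle = brentq(g, 0.9 * min(r_a, r_b), max(r_a, r_b) * 1.1, xtol=1e-14)
        assert sigma == pytest.approx(sigma_oracle, abs=1e-10)
        assert frac == pytest.approx(-lj(r_a, sigma), abs=1e-12)
        assert 0 < frac <= 1

    def test_classification_boundary(self):
        # similar distances share a deep well (common); dissimilar do not
        _, frac_close = mb.solve_isoenergetic_sigma(1.0, 1.2)
        _, frac_far = mb.solve_isoenergetic_sigma(1.0, 2.0)
        assert frac_close > 0.5
        assert frac_far < 0.5

    def test_symmetry_in_arguments(self):
        s1, f1 = mb.solve_isoenergetic_sigma(0.4, 0.5)
        s2, f2 = mb.solve_isoenergetic_sigma(0.5, 0.4)
        assert s1 == pytest.approx(s2)
        assert f1 == pytest.approx(f2)

    def test_nonpositive_distance_errors(self):
        with pytest.raises(mb.TopologyError):
            mb.solve_isoenergetic_sigma(-1.0, 1.0)


def _line_structure(positions, residue_indices, chain="L"):
    n = len(positions)
    return MolecularStructure(
        serials=list(range(1, n + 1)),
        names=["B1"] * n,
        elements=["C"] * n,
        residue_index=residue_indices,
        residue_names=["TOY"] * n,
        chain_ids=[chain] * n,
        positions=np.asarray(positions, dtype=float),
        subunits=["LSU"] * n,
    )


class TestContactMap:
    def test_pair_within_cutoff_and_sequence_separation(self):
        s = _line_structure([[0, 0, 0], [0.3, 0, 0]], [1, 5])
        params = mb.ForceFieldParams()
        contacts = mb.compute_contact_map(s, params, bonds=[])
        assert contacts == [(1, 2, pytest.approx(0.3))]

    def test_close_residues_excluded(self):
        s = _line_structure([[0, 0, 0], [0.3, 0, 0]], [1, 2])
        contacts = mb.compute_contact_map(s, mb.ForceFieldParams(), bonds=[])
        assert contacts == []

    def test_bonded_pair_never_contact(self):
        s = _line_structure([[0, 0, 0], [0.3, 0, 0]], [1, 5])
        contacts = mb.compute_contact_map(s, mb.ForceFieldParams(), bonds=[(1, 2)])
        assert contacts == []

    def test_shadow_occlusion_removes_blocked_pair(self):
        """A third atom on the segment midpoint occludes the line of sight."""
        s = _line_structure(
            [[0, 0, 0], [0.5, 0, 0], [0.25, 0.0, 0.0]], [1, 9, 5]
        )
        open_map = mb.compute_contact_map(
            s, mb.ForceFieldParams(shadow=False), bonds=[]
        )
        shadowed = mb.compute_contact_map(
            s, mb.ForceFieldParams(shadow=True), bonds=[]
        )
        assert (1, 2, pytest.approx(0.5)) in open_map
        assert not any(i == 1 and j == 2 for i, j, _ in shadowed)


class TestSingleBasin:
    def test_sigma_is_096_of_native_distance(self, toy_pair, params):
        rotated, _, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        for c in top.contacts:
            assert c.sigma / c.sigma_prime == pytest.approx(0.96, abs=1e-12)

    def test_all_terms_at_minimum_for_source_structure(self, toy_pair, params):
        from mbrot.dynamics import potential_energy

        rotated, _, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        _, breakdown = potential_energy(top, rotated.positions)
        assert breakdown["bonds"] == pytest.approx(0.0, abs=1e-18)
        assert breakdown["angles"] == pytest.approx(0.0, abs=1e-18)
        assert breakdown["dihedrals"] == pytest.approx(0.0, abs=1e-15)
        # contacts sit at 0.96 sigma' so each is slightly above its -eps floor
        depth = sum(c.eps * lj(c.sigma_prime, c.sigma) for c in top.contacts)
        assert breakdown["contacts"] == pytest.approx(depth, rel=1e-9)

    def test_untyped_residue_errors(self, toy_pair, params):
        rotated, _, truth = toy_pair
        bad = rotated.subset(np.ones(rotated.n_atoms, dtype=bool))
        bad.polymer_types = np.asarray(["mystery"] * bad.n_atoms, dtype=object)
        with pytest.raises(mb.TopologyError, match="untyped"):
            mb.build_single_basin(bad, params, bonds=truth.bonds)


class TestDihedralStrengths:
    def test_equal_division_within_group(self, toy_pair, params):
        rotated, _, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        groups = {}
        for d in top.proper_dihedrals:
            groups.setdefault(d.group, []).append(d.weight)
        for weights in groups.values():
            assert np.ptp(weights) < 1e-12  # every member shares the group weight

    @pytest.mark.parametrize(
        "polymer,expected_ratio", [("protein", 2.0), ("nucleic_acid", 1.0)]
    )
    def test_backbone_sidechain_ratio(self, polymer, expected_ratio, params):
        spec = toy_systems.ToySpec(polymer_type=polymer, seed=3)
        rotated, _, truth = toy_systems.make_two_state_toy(spec)
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        ratio = top.sum_dihedral_weights("bb") / top.sum_dihedral_weights("sc")
        assert ratio == pytest.approx(expected_ratio, abs=1e-10)

    def test_no_dihedrals_errors(self, four_atom_structure, params):
        top = mb.Topology(atoms=four_atom_structure)
        with pytest.raises(mb.TopologyError):
            mb.assign_dihedral_strengths(top, params)


class TestNormalization:
    def test_global_identities(self, toy_pair, params):
        rotated, _, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        sum_c = top.sum_contact_weights()
        sum_d = top.sum_dihedral_weights()
        n = rotated.n_atoms
        assert sum_c / sum_d == pytest.approx(2.0, abs=1e-10)
        assert sum_c + sum_d == pytest.approx(n * params.eps_reduced, abs=1e-10)

    def test_contact_share_of_budget(self, toy_pair, params):
        # with R = 2 the contacts carry 2/3 of the N*eps stabilizing energy
        rotated, _, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        n = rotated.n_atoms
        assert top.sum_contact_weights() == pytest.approx(n * 2.0 / 3.0, abs=1e-10)

    def test_zero_contacts_errors(self, toy_pair, params):
        rotated, _, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        top.contacts = []
        with pytest.raises(mb.TopologyError):
            mb.normalize_energies(top, params)


class TestCircularMean:
    def test_symmetric_mean(self):
        mean = mb.circular_mean(np.radians(10), np.radians(30))
        assert np.degrees(mean) == pytest.approx(20.0)

    def test_wraps_across_pi(self):
        mean = mb.circular_mean(np.radians(170), np.radians(-170))
        assert np.degrees(mean) == pytest.approx(180.0, abs=1e-9) or np.degrees(
            mean
        ) == pytest.approx(-180.0, abs=1e-9)

    def test_antipodal_errors(self):
        with pytest.raises(mb.TopologyError, match="antipodal"):
            mb.circular_mean(0.0, np.pi)


class TestMergeBasins:
    def test_identical_endpoints_all_common(self, toy_pair, params):
        rotated, _, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds, normalize=False)
        merged = mb.merge_basins(top, top, rotated, rotated, params)
        assert merged.contacts_of_class("rotated_unique") == []
        assert merged.contacts_of_class("unrotated_unique") == []
        single = mb.build_single_basin(rotated, params, bonds=truth.bonds)
        assert merged.sum_contact_weights() == pytest.approx(
            single.sum_contact_weights(), abs=1e-9
        )

    def test_dihedral_minimum_is_circular_mean(self, toy_pair, params, merged_topology):
        """Endpoint dihedral values are symmetric about the merged minimum,
        so the F_D energy is identical in the two endpoints."""
        rotated, unrotated, truth = toy_pair
        idx = {int(s): k for k, s in enumerate(rotated.serials)}
        fd = lambda x: (1 - np.cos(x)) + 0.5 * (1 - np.cos(3 * x))  # noqa: E731
        for d in merged_topology.proper_dihedrals[::7]:
            atoms = [idx[a] for a in (d.i, d.j, d.k, d.l)]
            phi_rot = mb.dihedral_angle(*rotated.positions[atoms])
            phi_unrot = mb.dihedral_angle(*unrotated.positions[atoms])
            assert fd(phi_rot - d.phi0) == pytest.approx(
                fd(phi_unrot - d.phi0), abs=1e-9
            )

    def test_common_contacts_isoenergetic(self, merged_topology):
        for c in merged_topology.contacts_of_class("common"):
            if c.r_native_a is None or c.r_native_b is None:
                continue
            v_a = lj(c.r_native_a, c.sigma_prime)
            v_b = lj(c.r_native_b, c.sigma_prime)
            assert abs(v_a - v_b) < 1e-9

    def test_unique_weights(self, merged_topology, params):
        for c in merged_topology.contacts_of_class("rotated_unique"):
            assert c.eps == params.w_rotated_unique
        for c in merged_topology.contacts_of_class("unrotated_unique"):
            assert c.eps == params.w_unrotated_unique
        assert merged_topology.contacts_of_class("rotated_unique")
        assert merged_topology.contacts_of_class("unrotated_unique")

    def test_classification_matches_brute_force(self, toy_pair, params, merged_topology):
        """Exhaustively reclassify every merged inter-domain pair from the
        raw endpoint coordinates."""
        rotated, unrotated, _ = toy_pair
        map_rot = dict(
            ((i, j), r) for i, j, r in mb.compute_contact_map(rotated, params)
        )
        map_unrot = dict(
            ((i, j), r) for i, j, r in mb.compute_contact_map(unrotated, params)
        )
        idx = {int(s): k for k, s in enumerate(rotated.serials)}
        for c in merged_topology.contacts:
            key = (c.i, c.j)
            inter = rotated.subunits[idx[c.i]] != rotated.subunits[idx[c.j]]
            if not inter:
                assert c.contact_class == "common"
                continue
            if key in map_rot and key in map_unrot:
                _, frac = mb.solve_isoenergetic_sigma(map_rot[key], map_unrot[key])
                if frac > 0.5:
                    assert c.contact_class == "common"
                elif map_rot[key] <= map_unrot[key]:
                    assert c.contact_class == "rotated_unique"
                else:
                    assert c.contact_class == "unrotated_unique"
            elif key in map_rot:
                assert c.contact_class == "rotated_unique"
            else:
                assert c.contact_class == "unrotated_unique"

    def test_swap_symmetry(self, toy_pair, params):
        """Swapping the endpoint labels exchanges the unique classes."""
        rotated, unrotated, truth = toy_pair
        top_r = mb.build_single_basin(rotated, params, bonds=truth.bonds, normalize=False)
        top_u = mb.build_single_basin(unrotated, params, bonds=truth.bonds, normalize=False)
        forward = mb.merge_basins(top_r, top_u, rotated, unrotated, params)
        swapped = mb.merge_basins(top_u, top_r, unrotated, rotated, params)
        fwd_rot = {(c.i, c.j) for c in forward.contacts_of_class("rotated_unique")}
        swp_unrot = {(c.i, c.j) for c in swapped.contacts_of_class("unrotated_unique")}
        assert fwd_rot == swp_unrot

    def test_normalization_survives_merge(self, toy_pair, params, merged_topology):
        rotated = toy_pair[0]
        n = rotated.n_atoms
        sum_c = merged_topology.sum_contact_weights()
        sum_d = merged_topology.sum_dihedral_weights()
        assert sum_c / sum_d == pytest.approx(params.R_C_over_D, abs=1e-10)
        assert sum_c + sum_d == pytest.approx(n * params.eps_reduced, abs=1e-10)

    def test_atom_table_mismatch_errors(self, toy_pair, params):
        rotated, unrotated, truth = toy_pair
        top = mb.build_single_basin(rotated, params, bonds=truth.bonds, normalize=False)
        smaller = rotated.subset(np.arange(rotated.n_atoms - 4))
        with pytest.raises(mb.TopologyError, match="atom table"):
            mb.merge_basins(top, top, rotated, smaller, params)
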