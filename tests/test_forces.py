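"""Force/energy consistency, neighbour search, and wall interactions."""

import numpy as np
import pytest

from mesocat import _kernels
from mesocat.geometry import (
    Boundary,
    CatalystLayout,
    EscapedParticleError,
    place_catalysts_planar,
    wall_energy,
)
from mesocat.integrate import ModelParams, compute_forces, potential_energy
from mesocat.model import IntegratorParams, PairParams
from mesocat.system import System, build_linear_chain

CUT = 2.0 ** (1.0 / 6.0)


def _random_chain_system(rng, n_chains=3, n_m=8, boundary=None):
    if boundary is None:
        boundary = Boundary.bulk(6.0)
    s = System.empty()
    for c in range(n_chains):
        origin = rng.uniform(5, boundary.box[0] - 12, 3)
        pos, lab = build_linear_chain(n_m, origin=origin, jitter=0.05, rng=rng)
        s.add_molecule(pos, np.zeros((n_m, 3)), lab)
    return s, boundary


class TestForceEnergyConsistency:
    @pytest.mark.parametrize("geometry", ["bulk", "flat_wall", "slit", "cylinder"])
    def test_forces_match_finite_differences(self, rng, geometry):
        """Central finite differences of the total energy reproduce the
        analytic forces to 1e-6 relative in every geometry."""
        if geometry == "bulk":
            b = Boundary.bulk(6.0)
        elif geometry == "flat_wall":
            b = Boundary.flat_wall(8.0, 6.0, 6.0)
        elif geometry == "slit":
            b = Boundary.slit(2.0, l_nm=4.0, Lout_nm=4.0, Ly_nm=5.0, Lz_nm=5.0)
        else:
            b = Boundary.cylinder(1.5, l_nm=4.0, Lout_nm=4.0, Ly_nm=5.0, Lz_nm=5.0)
        s = System.empty()
        mp = ModelParams(k_angle=5.09)
        # place a short chain in the open part of the domain
        if geometry == "bulk":
            origin = (10.0, 10.0, 10.0)
        elif geometry == "flat_wall":
            origin = (1.0, 5.0, 14.0)
        else:
            origin = (27.0, 8.0, 16.3)
        pos, lab = build_linear_chain(8, origin=origin, jitter=0.08, rng=rng)
        s.add_molecule(pos, np.zeros((8, 3)), lab)
        # one harmonic reaction bond between chain ends
        s.add_bond(0, 7, 1)
        F = compute_forces(s, b, mp)
        h = 1e-6
        checks = 0
        for bead in range(8):
            for dim in range(3):
                s.pos[bead, dim] += h
                ep = potential_energy(s, b, mp)
                s.pos[bead, dim] -= 2 * h
                em = potential_energy(s, b, mp)
                s.pos[bead, dim] += h
                fd = -(ep - em) / (2 * h)
                scale = max(1.0, abs(F[bead, dim]))
                assert abs(fd - F[bead, dim]) / scale < 1e-6
                checks += 1
        assert checks == 24

    def test_forces_with_catalyst_core_and_tether(self, rng):
        b = Boundary.flat_wall(8.0, 6.0, 6.0)
        layout = place_catalysts_planar(1, b, rng)
        s = System.empty()
        pos, lab = build_linear_chain(6, origin=(4.0, 9.0, 9.0), jitter=0.05,
                                      rng=rng)
        s.add_molecule(pos, np.zeros((6, 3)), lab)
        s.tethers[0] = 2  # tether a bead to site 0
        s.invalidate()
        mp = ModelParams(k_angle=5.09)
        F = compute_forces(s, b, mp, layout)
        h = 1e-6
        for bead in (0, 2, 5):
            for dim in range(3):
                s.pos[bead, dim] += h
                ep = potential_energy(s, b, mp, layout)
                s.pos[bead, dim] -= 2 * h
                em = potential_energy(s, b, mp, layout)
                s.pos[bead, dim] += h
                fd = -(ep - em) / (2 * h)
                assert abs(fd - F[bead, dim]) / max(1.0, abs(F[bead, dim])) < 1e-6

    def test_newtons_third_law_and_momentum(self, rng):
        s, b = _random_chain_system(rng)
        F = compute_forces(s, b, ModelParams(k_angle=3.0))
        # bulk periodic, internal forces only: total momentum change is zero
        assert np.abs(F.sum(axis=0)).max() < 1e-9

    def test_two_beads_at_cutoff_feel_no_force(self):
        b = Boundary.bulk(6.0)
        s = System.empty()
        pos = np.array([[10.0, 10.0, 10.0], [10.0 + CUT, 10.0, 10.0]])
        for i in range(2):
            s.add_molecule(pos[i][None, :], np.zeros((1, 3)),
                           np.array([False]))
        F = compute_forces(s, b, ModelParams())
        assert np.abs(F).max() < 1e-12


class TestNeighborSearch:
    def test_pair_at_half_sigma_listed(self):
        b = Boundary.bulk(6.0)
        pos = np.array([[5.0, 5.0, 5.0], [5.5, 5.0, 5.0]])
        pairs = _kernels.build_pairs(pos, b.box, b.pbc, 1.6)
        assert [0, 1] in pairs.tolist()

    def test_empty_system(self):
        b = Boundary.bulk(6.0)
        pairs = _kernels.build_pairs(np.zeros((0, 3)), b.box, b.pbc, 1.6)
        assert len(pairs) == 0

    def test_energy_matches_all_pairs_oracle(self, rng):
        """Cell-list energies equal a brute-force O(N^2) evaluation on a
        random 50-bead periodic configuration (including images)."""
        b = Boundary.bulk(2.0)  # ~13 sigma box: images matter
        n = 50
        pos = rng.uniform(0, 1, (n, 3)) * b.box
        pairs = _kernels.build_pairs(pos, b.box, b.pbc, CUT * 1.0001)
        p = PairParams()
        e_cell = 0.0
        for i, j in pairs:
            d = pos[i] - pos[j]
            d -= b.box * np.rint(d / b.box)
            r = np.linalg.norm(d)
            if r < p.cutoff:
                e_cell += float(
                    4 * p.epsilon * ((1 / r) ** 12 - (1 / r) ** 6) + p.epsilon
                )
        e_brute = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                d -= b.box * np.rint(d / b.box)
                r = np.linalg.norm(d)
                if r < p.cutoff:
                    e_brute += float(
                        4 * p.epsilon * ((1 / r) ** 12 - (1 / r) ** 6) + p.epsilon
                    )
        assert e_cell == pytest.approx(e_brute, rel=1e-12)


class TestWalls:
    def test_planar_wall_values(self):
        b = Boundary.flat_wall(8.0, 6.0, 6.0)
        assert wall_energy((CUT, 3.0, 3.0), b) == pytest.approx(0.0, abs=1e-12)
        assert wall_energy((1.0, 3.0, 3.0), b) == pytest.approx(0.833)
        assert wall_energy((20.0, 3.0, 3.0), b) == 0.0

    def test_cylinder_axis_is_field_free(self):
        b = Boundary.cylinder(1.5, l_nm=4.0, Lout_nm=4.0, Ly_nm=5.0, Lz_nm=5.0)
        centre = (10.0, b.box[1] / 2, b.box[2] / 2)
        assert wall_energy(centre, b) == 0.0

    def test_escaped_particle_raises(self):
        b = Boundary.flat_wall(8.0, 6.0, 6.0)
        with pytest.raises(EscapedParticleError):
            wall_energy((-0.5, 3.0, 3.0), b)

    def test_membrane_rim_blocks_corner_path(self):
        # a point diagonally off the slit rim sees the corner distance
        b = Boundary.slit(2.0, l_nm=4.0, Lout_nm=4.0, Ly_nm=5.0, Lz_nm=5.0)
        l = b.pore_length
        z_hi = b.wall_params[2]
        d = b.wall_distance((l / 0.1535 * 0.1535, 0.0, 0.0))  # smoke: callable
        p = np.array([l + 0.3, 1.0, z_hi - 0.4])
        assert b.wall_distance(p) == pytest.approx(np.hypot(0.3, 0.4))
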