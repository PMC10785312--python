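"""Selectivity, hydrodynamic radius, density probes and profiles."""

import numpy as np
import pytest

from mesocat.geometry import Boundary
from mesocat.observables import (
    AxialProfileAccumulator,
    DensityProbe,
    EndDensityAccumulator,
    EndToEndAccumulator,
    RHResult,
    UndefinedSelectivityError,
    hydrodynamic_radius,
    pooled_selectivity,
    probe_volume_nm3,
    selectivity,
    substrate_end_beads,
)
from mesocat.reaction import ReactionLedger
from mesocat.system import System, build_linear_chain
from mesocat.units import UNITS


def _ledger(n_rc, n_p):
    led = ReactionLedger()
    for i in range(n_rc):
        led.record(float(i), 0, "break_forward", "forward", 20, 1, "rc")
    for i in range(n_p):
        led.record(float(i), 0, "break_forward", "forward", 42, 2, "p")
    return led


class TestSelectivity:
    def test_even_split_gives_half(self):
        assert selectivity(_ledger(10, 10)).s_rc == 0.5

    def test_pure_ring_closing_gives_one(self):
        s = selectivity(_ledger(7, 0))
        assert s.s_rc == 1.0 and s.n_rc == 7

    def test_byproducts_and_transfers_excluded(self):
        led = _ledger(3, 1)
        led.record(9.0, 0, "break_forward", "forward", 2, 1, "byproduct")
        led.record(9.5, 0, "break_forward", "forward", 22, 1, "transfer")
        s = selectivity(led)
        assert s.n_rc + s.n_p == 4
        assert s.s_rc == pytest.approx(0.75)

    def test_no_productive_events_raises(self):
        with pytest.raises(UndefinedSelectivityError):
            selectivity(_ledger(0, 0))

    def test_pooling_counts_and_spread(self):
        pooled = pooled_selectivity([_ledger(6, 4), _ledger(2, 8)])
        assert pooled.s_rc == pytest.approx(8 / 20)
        assert pooled.std == pytest.approx(np.std([0.6, 0.2], ddof=1))
        # exact identity: S_RC * (N_RC + N_P) = N_RC
        assert pooled.s_rc * (pooled.n_rc + pooled.n_p) == pooled.n_rc


class TestHydrodynamicRadius:
    def test_two_beads_closed_form(self):
        """For two beads at fixed distance d the harmonic-mean pair
        distance is d itself."""
        d = 3.0
        conf = np.zeros((5, 2, 3))
        conf[:, 1, 0] = d
        rh = hydrodynamic_radius(conf)
        assert rh.r_h_nm == pytest.approx(UNITS.to_nm(d), rel=1e-12)

    def test_equilateral_triangle_closed_form(self):
        """All three pair distances equal a: R_H = a."""
        a = 2.0
        tri = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0]])
        rh = hydrodynamic_radius(tri[None, :, :])
        assert rh.r_h_nm == pytest.approx(UNITS.to_nm(a), rel=1e-12)

    def test_matches_bruteforce_double_sum(self, rng):
        """The estimator equals the explicit double-sum oracle on random
        conformers to machine precision."""
        conf = rng.normal(size=(10, 7, 3)) * 2.0
        rh = hydrodynamic_radius(conf)
        n = 7
        acc = []
        for c in conf:
            tot = 0.0
            for i in range(n):
                for j in range(n):
                    if i != j:
                        tot += 1.0 / np.linalg.norm(c[i] - c[j])
            acc.append(tot / (n * (n - 1)))
        oracle = 1.0 / np.mean(acc)
        assert rh.r_h_nm == pytest.approx(UNITS.to_nm(oracle), rel=1e-12)

    def test_coincident_beads_error(self):
        conf = np.zeros((1, 3, 3))
        with pytest.raises(FloatingPointError):
            hydrodynamic_radius(conf)


class TestDensityProbe:
    def test_window_bounds(self):
        p = DensityProbe()
        assert p.lo_nm == pytest.approx(0.4)
        assert p.hi_nm == pytest.approx(1.0)

    def test_probe_volumes_per_geometry(self):
        p = DensityProbe()
        flat = Boundary.flat_wall()
        assert probe_volume_nm3(p, flat) == pytest.approx(0.6 * 10.21**2)
        cyl = Boundary.cylinder(2.0, l_nm=10.0)
        expect = np.pi * ((2.0 - 0.4) ** 2 - (2.0 - 1.0) ** 2) * 10.0
        assert probe_volume_nm3(p, cyl) == pytest.approx(expect)
        with pytest.raises(ValueError):
            probe_volume_nm3(p, Boundary.cylinder(0.9))

    def test_uniform_gas_reads_bulk_density(self, rng):
        """Terminal beads spread uniformly give back their own number
        density inside the window."""
        b = Boundary.flat_wall(16.0, 10.21, 10.21)
        acc = EndDensityAccumulator()
        n_mol = 400
        vol_nm3 = 16.0 * 10.21**2
        for _ in range(60):
            sys_ = System.empty()
            for _ in range(n_mol):
                org = rng.uniform(0, 1, 3) * b.box
                pos = np.stack([org, org + [0.97, 0, 0]])
                lab = np.array([True, True])
                sys_.add_molecule(pos, np.zeros((2, 3)), lab)
            acc.add_frame(sys_, b)
        # 2 terminal labeled beads per dimer
        expect = 2 * n_mol / vol_nm3
        assert acc.density_nm3(b) == pytest.approx(expect, rel=0.12)

    def test_end_beads_exclude_products_and_attached(self):
        sys_ = System.empty()
        pos, lab = build_linear_chain(6)
        sub = sys_.add_molecule(pos, np.zeros((6, 3)), lab)
        prod = sys_.add_molecule(pos + 10, np.zeros((6, 3)), lab, kind="rc")
        ends = substrate_end_beads(sys_)
        assert set(ends) == {0, 5}


class TestEndToEnd:
    def test_two_bead_chain_reads_bond_length(self):
        sys_ = System.empty()
        pos = np.array([[0.0, 0, 0], [0.97, 0, 0]])
        sys_.add_molecule(pos, np.zeros((2, 3)), np.array([True, True]))
        acc = EndToEndAccumulator()
        acc.add_frame(sys_)
        assert acc.mean_nm() == pytest.approx(UNITS.to_nm(0.97))

    def test_stiff_library_approaches_rod_limit(self):
        from mesocat.gcmc import sample_conformer_library

        lib = sample_conformer_library(
            6, k_angle=1000.0, n_samples=120, seed=3, min_stride=200
        )
        e2e_nm = UNITS.to_nm(lib.end_to_end_distances().mean())
        assert e2e_nm == pytest.approx(UNITS.to_nm(5 * 0.97), rel=0.02)


class TestAxialProfile:
    def test_empty_system_gives_zero_profile(self):
        b = Boundary.slit(3.0, l_nm=6.0, Lout_nm=6.0, Ly_nm=5.0, Lz_nm=5.0)
        acc = AxialProfileAccumulator(n_bins=5)
        acc.add_frame(System.empty(), b)
        _, prof = acc.profile_nm3(b)
        assert np.all(prof == 0)

    def test_profile_normalization(self, rng):
        """Integral of the profile times the open cross-section recovers
        the mean in-pore substrate bead count exactly."""
        b = Boundary.slit(3.0, l_nm=6.0, Lout_nm=6.0, Ly_nm=5.0, Lz_nm=5.0)
        z_lo, z_hi = b.wall_params[1], b.wall_params[2]
        acc = AxialProfileAccumulator(n_bins=6)
        total = 0
        for _ in range(10):
            sys_ = System.empty()
            for _ in range(30):
                org = np.array(
                    [
                        rng.uniform(0, b.pore_length),
                        rng.uniform(0, b.box[1]),
                        rng.uniform(z_lo, z_hi),
                    ]
                )
                sys_.add_molecule(org[None, :], np.zeros((1, 3)),
                                  np.array([False]))
            total += sys_.n_beads
            acc.add_frame(sys_, b)
        centres, prof = acc.profile_nm3(b)
        assert len(centres) == 6
        cross_nm2 = UNITS.to_nm(b.box[1]) * UNITS.to_nm(b.pore_size)
        bin_w = UNITS.to_nm(b.pore_length) / 6
        integral = np.sum(prof) * bin_w * cross_nm2
        assert integral == pytest.approx(total / 10, rel=1e-9)
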