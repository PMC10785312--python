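"""Grand-canonical reservoir: conformer statistics, acceptance rules,
ideal-gas occupancy, purge semantics."""

import numpy as np
import pytest
from scipy import stats

from mesocat.fixtures import point_particle_library, straight_chain_library
from mesocat.gcmc import (
    GrandCanonicalReservoir,
    ReservoirSpec,
    integrated_autocorr_time,
    sample_conformer_library,
)
from mesocat.geometry import Boundary, CatalystLayout
from mesocat.integrate import ModelParams
from mesocat.system import MOL_RC, MOL_SUBSTRATE, System
from mesocat.units import UNITS


def _reservoir(boundary, library, rho_nm3=0.015, seed=0, **kw):
    spec = ReservoirSpec.from_nm3(rho_nm3, **kw)
    return GrandCanonicalReservoir(
        boundary,
        CatalystLayout.empty(),
        spec,
        library,
        ModelParams(),
        np.random.default_rng(seed),
    )


class TestConformerLibrary:
    def test_interior_angle_distribution_is_boltzmann(self, lib22):
        """One interior angle per stored conformer follows the analytic
        single-angle density ~ sin(phi) exp(-K (phi - pi)^2 / 2)."""
        k = lib22.k_angle
        p = lib22.positions
        v1 = p[:, 9] - p[:, 10]
        v2 = p[:, 11] - p[:, 10]
        c = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        phi = np.arccos(np.clip(c, -1, 1))
        grid = np.linspace(0, np.pi, 4001)
        dens = np.sin(grid) * np.exp(-0.5 * k * (grid - np.pi) ** 2)
        cdf_grid = np.cumsum(dens)
        cdf_grid /= cdf_grid[-1]

        def cdf(x):
            return np.interp(x, grid, cdf_grid)

        res = stats.kstest(phi, cdf)
        assert res.pvalue > 0.01

    def test_rigid_rod_limit(self):
        """Very stiff chains approach the straight-rod end-to-end length."""
        lib = sample_conformer_library(
            8, k_angle=1000.0, n_samples=150, seed=2, min_stride=200
        )
        e2e = lib.end_to_end_distances().mean()
        assert e2e == pytest.approx(7 * 0.97, rel=0.02)

    def test_bonds_never_diverged(self, lib22):
        b = np.linalg.norm(np.diff(lib22.positions, axis=1), axis=2)
        assert b.max() < 1.5
        assert b.mean() == pytest.approx(0.97, abs=0.02)

    def test_save_load_roundtrip(self, tmp_path, lib22):
        path = tmp_path / "lib.npz"
        lib22.save(path)
        from mesocat.gcmc import ConformerLibrary

        back = ConformerLibrary.load(path)
        np.testing.assert_array_equal(back.positions, lib22.positions)
        assert back.k_angle == lib22.k_angle

    def test_autocorr_time_of_white_noise_is_half(self, rng):
        x = rng.normal(size=20_000)
        assert integrated_autocorr_time(x) == pytest.approx(0.5, abs=0.1)


class TestIdealGasReservoir:
    def test_insertion_acceptance_into_empty_box(self):
        """Empty ideal box: acceptance probability is min(1, rho V_c)
        per attempt (here < 1 via a tiny box)."""
        b = Boundary.bulk(3.0)
        res = _reservoir(b, point_particle_library(), rho_nm3=0.015, seed=4)
        n_try = 4000
        acc = 0
        for _ in range(n_try):
            sys_ = System.empty()
            if res.attempt_insertion(sys_):
                acc += 1
        expect = res.spec.rho_res * res.volume  # = 0.405 molecules
        assert acc / n_try == pytest.approx(expect, rel=0.1)

    def test_occupancy_is_poisson(self):
        """Stationary molecule count in the coupled box is Poisson with
        mean rho V (chi-square at alpha = 0.01); variance/mean ~ 1."""
        b = Boundary.bulk(10.0)
        res = _reservoir(b, point_particle_library(), rho_nm3=0.015, seed=4)
        mean = res.spec.rho_res * res.volume
        sys_ = System.empty()
        for _ in range(300):  # burn-in
            res.sweep(sys_, 20)
        counts = []
        for _ in range(3000):
            res.sweep(sys_, 20)
            counts.append(len(sys_.molecules(MOL_SUBSTRATE)))
        counts = np.asarray(counts[::3])  # thin for independence
        assert counts.mean() == pytest.approx(mean, rel=0.05)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.15)
        # chi-square against the exact Poisson pmf
        lo, hi = int(mean - 3 * np.sqrt(mean)), int(mean + 3 * np.sqrt(mean))
        edges = list(range(lo, hi + 1))
        obs = np.array(
            [np.sum(counts == k) for k in edges], dtype=float
        )
        obs = np.concatenate(
            [[np.sum(counts < lo)], obs, [np.sum(counts > hi)]]
        )
        pmf = stats.poisson.pmf(edges, mean)
        probs = np.concatenate(
            [[stats.poisson.cdf(lo - 1, mean)], pmf,
             [stats.poisson.sf(hi, mean)]]
        )
        chi2 = np.sum((obs - len(counts) * probs) ** 2 / (len(counts) * probs))
        dof = len(obs) - 1
        assert chi2 < stats.chi2.ppf(0.99, dof)

    def test_deletion_noop_on_empty_system(self):
        b = Boundary.bulk(5.0)
        res = _reservoir(b, point_particle_library())
        sys_ = System.empty()
        assert not res.attempt_deletion(sys_)


class TestEligibilityAndPurge:
    def test_straddling_molecule_ineligible(self):
        b = Boundary.flat_wall(16.0, 6.0, 6.0)
        lib = straight_chain_library(6)
        res = _reservoir(b, lib)
        sys_ = System.empty()
        # one molecule fully coupled, one straddling the coupling boundary
        inside = np.tile([UNITS.from_nm(12.0), 10.0, 10.0], (6, 1))
        inside[:, 0] += np.arange(6) * 0.97
        straddle = inside.copy()
        straddle[:, 0] = b.couple_dist + np.arange(6) * 0.97 - 2.0
        lab = np.zeros(6, bool)
        m1 = sys_.add_molecule(inside, np.zeros((6, 3)), lab)
        m2 = sys_.add_molecule(straddle, np.zeros((6, 3)), lab)
        assert res.eligible_substrates(sys_) == [m1]

    def test_purge_removes_only_coupled_products(self):
        b = Boundary.flat_wall(16.0, 6.0, 6.0)
        res = _reservoir(b, straight_chain_library(4))
        sys_ = System.empty()
        lab = np.zeros(4, bool)
        coupled = np.tile([UNITS.from_nm(12.0), 10.0, 10.0], (4, 1))
        coupled[:, 0] += np.arange(4) * 0.97
        buffer_ = coupled.copy()
        buffer_[:, 0] = 5.0 + np.arange(4) * 0.97
        ring = sys_.add_molecule(coupled, np.zeros((4, 3)), lab, kind=MOL_RC)
        ring_in_pore = sys_.add_molecule(buffer_, np.zeros((4, 3)), lab,
                                         kind=MOL_RC)
        substrate = sys_.add_molecule(
            coupled + np.array([3.0, 0, 0]), np.zeros((4, 3)), lab,
            kind=MOL_SUBSTRATE,
        )
        n = res.purge_products(sys_)
        assert n == 1
        assert ring not in sys_.mol_kind
        assert ring_in_pore in sys_.mol_kind  # retained: not coupled
        assert substrate in sys_.mol_kind  # substrates are never purged

    def test_zero_attempt_sweep_is_identity(self):
        b = Boundary.bulk(5.0)
        res = _reservoir(b, point_particle_library())
        sys_ = System.empty()
        res.sweep(sys_, 0)
        assert sys_.n_beads == 0

    def test_move_accounting(self):
        b = Boundary.bulk(6.0)
        res = _reservoir(b, point_particle_library(), seed=11)
        sys_ = System.empty()
        for _ in range(50):
            res.sweep(sys_, 10)
        st = res.stats
        assert st.attempted_insert + st.attempted_delete == 500
        assert 0 < st.accepted_insert <= st.attempted_insert
        assert st.accepted_delete <= st.attempted_delete
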