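"""Grand-canonical reservoir coupling.

Substrate molecules are exchanged with an ideal reservoir of number
density ``rho_res`` inside the coupled region only.  Whole molecules are
inserted in Boltzmann-distributed single-chain conformations drawn from a
pre-sampled library (so the *internal* energy is already canonically
distributed and only the intermolecular, wall and catalyst-core energy
enters the Metropolis weight), and deleted with the matching reverse
acceptance, which together satisfy detailed balance with respect to the
grand-canonical distribution at zero excess chemical potential:

    acc(insert) = min(1, rho V_c / (N + 1) * exp(-beta dE_inter))
    acc(delete) = min(1, N / (rho V_c) * exp(+beta E_inter))

The thermal wavelength / normalization constant is absorbed into the
activity by writing the acceptance directly in terms of the target
reservoir density.  Products (rings, polymerized chains, byproducts) have
chemical potential minus infinity: they are removed unconditionally once
they are fully inside the coupled region and are never inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import (
    Boundary,
    CatalystLayout,
    coupled_mask,
    coupled_volume,
    region_membership,
    sample_coupled_point,
)
from .integrate import MDDriver, ModelParams, draw_maxwell_velocities
from .model import AngleParams, IntegratorParams, angle_stiffness_for
from .system import (
    MOL_BYPRODUCT,
    MOL_P,
    MOL_RC,
    MOL_SUBSTRATE,
    System,
    build_linear_chain,
)
from .units import UNITS


class SamplingQualityError(RuntimeError):
    """Single-chain sampling did not decorrelate."""


@dataclass
class ConformerLibrary:
    """Boltzmann-sampled single-chain configurations (reduced units).

    ``positions`` is (n_conformers, N_m, 3), each conformer centred at its
    centre of mass.  ``energies`` holds the internal (bonded + bending +
    intramolecular WCA) energy of each stored conformer.
    """

    n_monomers: int
    k_angle: float
    positions: np.ndarray
    energies: np.ndarray
    stride_steps: int
    seed: int

    @property
    def n_conformers(self) -> int:
        return len(self.positions)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            n_monomers=self.n_monomers,
            k_angle=self.k_angle,
            positions=self.positions,
            energies=self.energies,
            stride_steps=self.stride_steps,
            seed=self.seed,
        )

    @staticmethod
    def load(path) -> "ConformerLibrary":
        d = np.load(path)
        return ConformerLibrary(
            n_monomers=int(d["n_monomers"]),
            k_angle=float(d["k_angle"]),
            positions=d["positions"],
            energies=d["energies"],
            stride_steps=int(d["stride_steps"]),
            seed=int(d["seed"]),
        )

    def end_to_end_distances(self) -> np.ndarray:
        return np.linalg.norm(self.positions[:, -1] - self.positions[:, 0], axis=1)


def integrated_autocorr_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time (in sample units) via FFT with a
    self-consistent window cutoff."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    f = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    if acf[0] <= 0:
        return 0.5
    acf /= acf[0]
    tau = 0.5
    for t in range(1, n):
        tau += acf[t]
        if t >= 6.0 * tau:  # standard windowing
            break
    return max(float(tau), 0.5)


def sample_conformer_library(
    n_monomers: int,
    k_angle: float | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
    mp: ModelParams | None = None,
    ip: IntegratorParams | None = None,
    equil_steps: int = 50_000,
    pilot_samples: int = 4_000,
    pilot_stride: int = 50,
    min_stride: int = 500,
) -> ConformerLibrary:
    """Sample decorrelated single-chain conformers by Langevin dynamics.

    A pilot run measures the end-to-end autocorrelation time; production
    snapshots are then taken every ``>= 2x`` that time.  Raises
    :class:`SamplingQualityError` if the pilot run is too short to resolve
    the autocorrelation time.
    """
    if k_angle is None:
        k_angle = angle_stiffness_for(n_monomers)
    if mp is None:
        mp = ModelParams(k_angle=k_angle)
    else:
        mp = ModelParams(pair=mp.pair, fene=mp.fene, harmonic=mp.harmonic,
                         k_angle=k_angle)
    if ip is None:
        ip = IntegratorParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F]))
    box_size = max(4.0 * n_monomers, 60.0)
    boundary = Boundary.open_box(UNITS.to_nm(box_size))
    system = System.empty()
    pos, labeled = build_linear_chain(
        n_monomers, origin=(box_size / 2 - n_monomers / 2, box_size / 2, box_size / 2),
        jitter=0.01, rng=rng,
    )
    system.add_molecule(
        pos, draw_maxwell_velocities(n_monomers, ip.temperature, rng), labeled
    )
    driver = MDDriver(system, boundary, mp, ip, seed=seed)
    driver.run(equil_steps)
    # pilot: estimate the end-to-end decorrelation
    e2e = np.empty(pilot_samples)
    for i in range(pilot_samples):
        driver.run(pilot_stride)
        e2e[i] = np.linalg.norm(system.pos[-1] - system.pos[0])
    tau_samples = integrated_autocorr_time(e2e)
    if tau_samples > pilot_samples / 20.0:
        raise SamplingQualityError(
            f"end-to-end autocorrelation time ({tau_samples:.0f} pilot samples) "
            "not resolved; increase pilot length"
        )
    stride = max(min_stride, int(np.ceil(2.0 * tau_samples * pilot_stride)))
    confs = np.empty((n_samples, n_monomers, 3))
    box = boundary.box
    for i in range(n_samples):
        driver.run(stride)
        # unwrap across the periodic box by walking the backbone
        p = system.pos.copy()
        for b in range(1, n_monomers):
            d = p[b] - p[b - 1]
            d -= box * np.rint(d / box)
            p[b] = p[b - 1] + d
        confs[i] = p - p.mean(axis=0)
    energies = _internal_energies(confs, mp)
    return ConformerLibrary(
        n_monomers=n_monomers,
        k_angle=k_angle,
        positions=confs,
        energies=energies,
        stride_steps=stride,
        seed=seed,
    )


def _internal_energies(confs: np.ndarray, mp: ModelParams) -> np.ndarray:
    """Internal (bonded + bending + intra-WCA) energy of each conformer."""
    from .model import angle_energy, fene_energy, wca_energy

    n = confs.shape[1]
    out = np.empty(len(confs))
    ap = AngleParams(K_angle=mp.k_angle)
    iu, ju = np.triu_indices(n, k=1)
    for c, p in enumerate(confs):
        d = np.linalg.norm(p[iu] - p[ju], axis=1)
        e = float(np.sum(wca_energy(d, mp.pair)))
        b = np.linalg.norm(np.diff(p, axis=0), axis=1)
        e += float(np.sum(fene_energy(b, mp.fene)))
        v1 = p[:-2] - p[1:-1]
        v2 = p[2:] - p[1:-1]
        cosphi = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        phi = np.arccos(np.clip(cosphi, -1.0, 1.0))
        e += float(np.sum(angle_energy(phi, ap)))
        out[c] = e
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass(frozen=True)
class ReservoirSpec:
    """Reservoir definition (densities in reduced sigma^-3).

    ``rho_res`` is the ideal-reservoir substrate number density; the
    substrate excess chemical potential is taken as zero (dilute limit)
    and the product chemical potential as minus infinity (unconditional
    removal).
    """

    rho_res: float
    attempts_per_sweep: int = 10
    sweep_interval: int = 100  # MD steps between sweeps

    @staticmethod
    def from_nm3(rho_per_nm3: float = 0.015, **kw) -> "ReservoirSpec":
        return ReservoirSpec(rho_res=UNITS.density_from_per_nm3(rho_per_nm3), **kw)

    @property
    def rho_res_nm3(self) -> float:
        return UNITS.density_to_per_nm3(self.rho_res)


@dataclass
class GCMCStats:
    attempted_insert: int = 0
    accepted_insert: int = 0
    attempted_delete: int = 0
    accepted_delete: int = 0
    purged: int = 0


class GrandCanonicalReservoir:
    """Insertion/deletion/purge machinery bound to one running system."""

    def __init__(
        self,
        boundary: Boundary,
        layout: CatalystLayout,
        spec: ReservoirSpec,
        library: ConformerLibrary,
        mp: ModelParams,
        rng: np.random.Generator,
        temperature: float = 1.0,
    ):
        self.boundary = boundary
        self.layout = layout
        self.spec = spec
        self.library = library
        self.mp = mp
        self.rng = rng
        self.temperature = temperature
        self.volume = coupled_volume(boundary, layout)
        self.stats = GCMCStats()
        #: callables invoked with the old->new bead index map after any
        #: molecule removal compacts the bead arrays
        self.compaction_listeners: list = []

    # -- eligibility -------------------------------------------------------
    def _coupled_mols(self, system: System, kinds: tuple) -> list[int]:
        if system.n_beads == 0:
            return []
        mask = coupled_mask(system.pos, self.boundary, self.layout)
        straddling = set(np.unique(system.mol_id[~mask]).tolist())
        out = []
        for kind in kinds:
            out.extend(
                m for m in system.molecules(kind) if m not in straddling
            )
        return sorted(out)

    def _fully_coupled(self, system: System, mol: int) -> bool:
        mask = coupled_mask(
            system.pos[system.mol_id == mol], self.boundary, self.layout
        )
        return bool(np.all(mask))

    def eligible_substrates(self, system: System) -> list[int]:
        """Substrate molecules entirely inside the coupled region."""
        return self._coupled_mols(system, (MOL_SUBSTRATE,))

    def substrate_density(self, system: System) -> float:
        """Instantaneous eligible-substrate density in V_c (sigma^-3)."""
        return len(self.eligible_substrates(system)) / self.volume

    # -- moves -------------------------------------------------------------
    def _external_energy(self, system: System, beads: np.ndarray,
                         exclude_mol: int) -> float:
        return float(
            _kernels.external_energy(
                np.ascontiguousarray(beads, dtype=np.float64),
                system.pos,
                system.mol_id,
                exclude_mol,
                self.boundary.box,
                self.boundary.pbc,
                self.boundary.wall_kind,
                self.boundary.wall_params,
                self.layout.core_pos,
                self.layout.core_radius,
                self.mp.pair.epsilon,
                self.mp.pair.sigma,
            )
        )

    def attempt_insertion(self, system: System) -> bool:
        self.stats.attempted_insert += 1
        rng = self.rng
        conf = self.library.positions[rng.integers(self.library.n_conformers)]
        rot = _random_rotation(rng)
        com = sample_coupled_point(self.boundary, rng, self.layout)
        beads = conf @ rot.T + com
        if not bool(np.all(coupled_mask(beads, self.boundary, self.layout))):
            return False
        n_el = len(self.eligible_substrates(system))
        de = self._external_energy(system, beads, exclude_mol=-2)
        if de > _kernels.E_CAP:
            return False
        ratio = self.spec.rho_res * self.volume / (n_el + 1) * np.exp(
            -de / self.temperature
        )
        if rng.random() >= min(1.0, ratio):
            return False
        # wrap into the primary box along periodic axes
        for d in range(3):
            if self.boundary.pbc[d]:
                beads[:, d] %= self.boundary.box[d]
        vel = draw_maxwell_velocities(len(beads), self.temperature, rng)
        _, labeled = build_linear_chain(self.library.n_monomers)
        system.add_molecule(beads, vel, labeled, kind=MOL_SUBSTRATE)
        self.stats.accepted_insert += 1
        return True

    def attempt_deletion(self, system: System) -> bool:
        self.stats.attempted_delete += 1
        rng = self.rng
        eligible = self.eligible_substrates(system)
        n_el = len(eligible)
        if n_el == 0:
            return False
        mol = eligible[rng.integers(n_el)]
        beads = system.beads_of(mol)
        e_inter = self._external_energy(system, system.pos[beads], exclude_mol=mol)
        ratio = n_el / (self.spec.rho_res * self.volume) * np.exp(
            e_inter / self.temperature
        )
        if rng.random() >= min(1.0, ratio):
            return False
        new_index = system.remove_molecules([mol])
        for cb in self.compaction_listeners:
            cb(new_index)
        self.stats.accepted_delete += 1
        return True

    def purge_products(self, system: System) -> int:
        """Remove every product molecule fully inside the coupled region."""
        doomed = self._coupled_mols(system, (MOL_RC, MOL_P, MOL_BYPRODUCT))
        if doomed:
            new_index = system.remove_molecules(doomed)
            for cb in self.compaction_listeners:
                cb(new_index)
            self.stats.purged += len(doomed)
        return len(doomed)

    def sweep(self, system: System, n_attempts: int | None = None) -> None:
        """One reservoir sweep: exchange attempts plus a purge pass."""
        if n_attempts is None:
            n_attempts = self.spec.attempts_per_sweep
        for _ in range(n_attempts):
            if self.rng.random() < 0.5:
                self.attempt_insertion(system)
            else:
                self.attempt_deletion(system)
        self.purge_products(system)


def populate_region(
    system: System,
    boundary: Boundary,
    layout: CatalystLayout,
    spec: ReservoirSpec,
    library: ConformerLibrary,
    mp: ModelParams,
    rng: np.random.Generator,
    temperature: float = 1.0,
    everywhere: bool = True,
) -> int:
    """Initially fill the accessible volume with substrate at ``rho_res``.

    Molecules are placed anywhere in the accessible volume (not only the
    coupled region) so that a run starts near the reservoir density
    instead of waiting one box-diffusion time; overlapping trials are
    simply rejected.  Returns the number of molecules placed.
    """
    vol = boundary.volume if everywhere else coupled_volume(boundary, layout)
    target = rng.poisson(spec.rho_res * vol)
    placed = 0
    tries = 0
    while placed < target and tries < 100 * target + 100:
        tries += 1
        conf = library.positions[rng.integers(library.n_conformers)]
        rot = _random_rotation(rng)
        if everywhere:
            com = rng.uniform(0, 1, 3) * boundary.box
        else:
            com = sample_coupled_point(boundary, rng, layout)
        beads = conf @ rot.T + com
        if not everywhere:
            if not bool(np.all(coupled_mask(beads, boundary, layout))):
                continue
        de = float(
            _kernels.external_energy(
                np.ascontiguousarray(beads),
                system.pos,
                system.mol_id,
                -2,
                boundary.box,
                boundary.pbc,
                boundary.wall_kind,
                boundary.wall_params,
                layout.core_pos,
                layout.core_radius,
                mp.pair.epsilon,
                mp.pair.sigma,
            )
        )
        if de > 2.0:  # placement must be essentially relaxed
            continue
        for d in range(3):
            if boundary.pbc[d]:
                beads[:, d] %= boundary.box[d]
        vel = draw_maxwell_velocities(len(beads), temperature, rng)
        _, labeled = build_linear_chain(library.n_monomers)
        system.add_molecule(beads, vel, labeled, kind=MOL_SUBSTRATE)
        placed += 1
    return placed
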