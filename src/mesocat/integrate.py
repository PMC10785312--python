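"""Langevin dynamics driver.

The integrator is the BAOAB splitting of Langevin dynamics: two velocity
half-kicks and two half-drifts around an exact Ornstein-Uhlenbeck velocity
update.  At ``gamma = 0`` (and zero noise) it reduces to velocity Verlet,
so microcanonical energy conservation can be checked with the same code
path.  Thermostat noise is drawn per block from a stream seeded by
``(master seed, stream tag, global step index)``, which makes runs
bit-reproducible and checkpoint-restartable regardless of how the step
loop is chopped into blocks by reaction events or reservoir moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import Boundary, CatalystLayout
from .model import (
    AngleParams,
    DivergedBondError,
    FeneParams,
    HarmonicBondParams,
    IntegratorParams,
    PairParams,
)
from .system import System

#: Verlet skin added to the WCA cutoff for the neighbour list.
DEFAULT_SKIN = 0.9

#: Noise array budget per kernel call, in doubles.
_NOISE_BUDGET = 6_000_000

_NOISE_TAG = 0xA11CE
_CUT = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ModelParams:
    """All interaction parameters of a run, bundled."""

    pair: PairParams = field(default_factory=PairParams)
    fene: FeneParams = field(default_factory=FeneParams)
    harmonic: HarmonicBondParams = field(default_factory=HarmonicBondParams)
    k_angle: float = 0.0


@dataclass
class BlockResult:
    status: int  # 0 done, 1 binding event, 2 diverged bond, 3 escaped
    steps_done: int
    site: int = -1
    bead: int = -1


class IntegrationBlowupError(RuntimeError):
    pass


def _kernel_static_args(system: System, boundary: Boundary,
                        layout: CatalystLayout, mp: ModelParams):
    bonds, kinds = system.bond_arrays
    return (
        bonds,
        kinds,
        system.angle_array,
        system.tether_bead_array,
        system.tether_anchor_array(layout.site_pos),
        boundary.box,
        boundary.pbc,
        boundary.wall_kind,
        boundary.wall_params,
        layout.core_pos,
        layout.core_radius,
        mp.pair.epsilon,
        mp.pair.sigma,
        mp.fene.K,
        mp.fene.r_max,
        mp.harmonic.k,
        mp.harmonic.r0,
        mp.k_angle,
    )


def compute_forces(
    system: System,
    boundary: Boundary,
    mp: ModelParams,
    layout: CatalystLayout | None = None,
) -> np.ndarray:
    """Force on every bead (minus the total potential gradient)."""
    if layout is None:
        layout = CatalystLayout.empty()
    forces = np.zeros_like(system.pos)
    rlist = _CUT * mp.pair.sigma * 1.0001
    pairs = _kernels.build_pairs(system.pos, boundary.box, boundary.pbc, rlist)
    epot, status, a, b = _kernels.compute_forces(
        system.pos, forces, pairs,
        *_kernel_static_args(system, boundary, layout, mp), True,
    )
    if status == 2:
        raise DivergedBondError(a, b, float("nan"))
    if status == 3:
        raise IntegrationBlowupError(f"bead {a} escaped through a wall")
    return forces


def potential_energy(
    system: System,
    boundary: Boundary,
    mp: ModelParams,
    layout: CatalystLayout | None = None,
) -> float:
    if layout is None:
        layout = CatalystLayout.empty()
    epot, status = _kernels.total_energy(
        system.pos, *_kernel_static_args(system, boundary, layout, mp)
    )
    if status != 0:
        raise IntegrationBlowupError(f"invalid configuration (status {status})")
    return float(epot)


def kinetic_temperature(system: System) -> float:
    """Instantaneous kinetic temperature, 2 KE / (3 N) in reduced units."""
    if system.n_beads == 0:
        return 0.0
    return float(np.mean(system.vel**2))


def draw_maxwell_velocities(n: int, temperature: float,
                            rng: np.random.Generator) -> np.ndarray:
    return rng.normal(scale=np.sqrt(temperature), size=(n, 3))


class MDDriver:
    """Owns the step loop for one system.

    Blocks end early on reaction-triggering collisions (status 1); the
    caller applies the event and resumes.  ``global_step`` counts all MD
    steps ever taken and seeds the thermostat noise.
    """

    def __init__(
        self,
        system: System,
        boundary: Boundary,
        mp: ModelParams,
        ip: IntegratorParams,
        seed: int,
        layout: CatalystLayout | None = None,
        skin: float = DEFAULT_SKIN,
        global_step: int = 0,
    ):
        self.system = system
        self.boundary = boundary
        self.mp = mp
        self.ip = ip
        self.seed = int(seed)
        self.layout = layout if layout is not None else CatalystLayout.empty()
        self.skin = skin
        self.global_step = int(global_step)
        self._forces = np.zeros_like(system.pos)
        #: rare-event counter: FENE bonds pulled back from divergence
        #: after an energetic reaction cascade (see docs)
        self.bond_rescues = 0

    @property
    def rlist(self) -> float:
        return _CUT * self.mp.pair.sigma + self.skin

    def _noise(self, nsteps: int, n: int) -> np.ndarray:
        if self.ip.gamma == 0.0:
            return np.zeros((nsteps, n, 3))
        ss = np.random.SeedSequence([self.seed, _NOISE_TAG, self.global_step])
        rng = np.random.Generator(np.random.PCG64(ss))
        return rng.standard_normal((nsteps, n, 3))

    def run(
        self,
        nsteps: int,
        check_reactions: bool = False,
        site_accept: np.ndarray | None = None,
        capture_radius: float = 0.5,
    ) -> BlockResult:
        """Advance up to ``nsteps``; may stop early on a binding collision."""
        sys_ = self.system
        n = sys_.n_beads
        if n == 0:
            self.global_step += nsteps
            sys_.time += nsteps * self.ip.dt
            return BlockResult(0, nsteps)
        if self._forces.shape != sys_.pos.shape:
            self._forces = np.zeros_like(sys_.pos)
        if site_accept is None:
            site_accept = np.zeros(len(self.layout.site_pos), dtype=np.uint8)
        done = 0
        chunk_max = max(1, _NOISE_BUDGET // (3 * n))
        while done < nsteps:
            chunk = min(chunk_max, nsteps - done)
            noise = self._noise(chunk, n)
            status, steps, a, b = _kernels.md_block(
                sys_.pos,
                sys_.vel,
                self._forces,
                chunk,
                noise,
                self.ip.dt,
                self.ip.gamma,
                self.ip.temperature,
                *_kernel_static_args(sys_, self.boundary, self.layout, self.mp),
                self.rlist,
                self.layout.site_pos,
                site_accept,
                sys_.reactive_index_array,
                sys_.in_capture,
                capture_radius**2,
                check_reactions,
            )
            done += steps
            self.global_step += steps
            sys_.time += steps * self.ip.dt
            if status == 1:
                return BlockResult(1, done, site=int(a), bead=int(b))
            if status == 2:
                # a reaction-formed bond occasionally dumps enough energy
                # into a chain to push one FENE bond past r_max within a
                # single step; pull the pair back inside and re-thermalize
                # it rather than aborting the run
                self.bond_rescues += 1
                if self.bond_rescues > 10_000:
                    raise DivergedBondError(int(a), int(b), float("nan"))
                i, j = int(a), int(b)
                d = sys_.pos[i] - sys_.pos[j]
                box, pbc = self.boundary.box, self.boundary.pbc
                for dim in range(3):
                    if pbc[dim]:
                        d[dim] -= box[dim] * np.rint(d[dim] / box[dim])
                r = float(np.linalg.norm(d))
                target = 0.93 * self.mp.fene.r_max
                mid = sys_.pos[j] + 0.5 * d
                sys_.pos[i] = mid + 0.5 * target / r * d
                sys_.pos[j] = mid - 0.5 * target / r * d
                sys_.vel[i] = 0.0
                sys_.vel[j] = 0.0
                continue
            if status == 3:
                raise IntegrationBlowupError(
                    f"integration blowup at step {self.global_step} (bead {a})"
                )
        return BlockResult(0, done)
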