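"""End-to-end simulation orchestration.

A :class:`Runner` couples the Langevin integrator, the metathesis event
engine and the grand-canonical reservoir on one system:

- MD advances in blocks; a block ends early when a reactive bead collides
  with an accepting catalyst site, in which case the binding trial fires
  immediately (reaction checks happen every step).
- Metallacycle breakups execute at the first MD step past their drawn
  exponential waiting time.
- Every ``sweep_interval`` steps the reservoir performs its exchange
  attempts and purges products from the coupled region.

Randomness is split into independent per-purpose streams (thermostat
noise, reaction, reservoir, initial state) derived from one master seed,
so a run is bit-reproducible and restartable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gcmc import (
    ConformerLibrary,
    GrandCanonicalReservoir,
    ReservoirSpec,
    populate_region,
)
from .geometry import Boundary, CatalystLayout
from .integrate import MDDriver, ModelParams
from .model import IntegratorParams
from .reaction import (
    Catalyst,
    ReactionLedger,
    ReactionParams,
    apply_breakup,
    attempt_binding,
    choose_direction,
    initialize_catalysts,
    site_accept_array,
)
from .system import System

_STREAM_REACTION = 1
_STREAM_GCMC = 2
_STREAM_INIT = 3


@dataclass
class TimeSeries:
    """Scalar per-sample log (reduced units)."""

    time: list = field(default_factory=list)
    kinetic_temperature: list = field(default_factory=list)
    n_beads: list = field(default_factory=list)
    n_substrates_coupled: list = field(default_factory=list)

    def to_arrays(self) -> dict:
        return {k: np.asarray(v) for k, v in self.__dict__.items()}


class Runner:
    """One coupled MD + reaction + reservoir simulation."""

    def __init__(
        self,
        boundary: Boundary,
        layout: CatalystLayout,
        mp: ModelParams,
        ip: IntegratorParams,
        seed: int,
        rp: ReactionParams | None = None,
        reservoir_spec: ReservoirSpec | None = None,
        library: ConformerLibrary | None = None,
        reactions_on: bool = True,
        populate: bool = True,
    ):
        self.boundary = boundary
        self.layout = layout
        self.mp = mp
        self.ip = ip
        self.rp = rp if rp is not None else ReactionParams()
        self.seed = int(seed)
        self.reactions_on = reactions_on and layout.n_catalysts > 0
        self.rng_react = np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAM_REACTION])
        )
        self.rng_gcmc = np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAM_GCMC])
        )
        rng_init = np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAM_INIT])
        )
        self.system = System.empty()
        self.ledger = ReactionLedger()
        self.catalysts: list[Catalyst] = []
        if self.reactions_on:
            self.catalysts = initialize_catalysts(
                self.system, layout, rng_init, ip.temperature, self.mp.harmonic.r0
            )
        self.reservoir: GrandCanonicalReservoir | None = None
        if reservoir_spec is not None:
            if library is None:
                raise ValueError("a conformer library is required for GCMC")
            self.reservoir = GrandCanonicalReservoir(
                boundary, layout, reservoir_spec, library, mp, self.rng_gcmc,
                ip.temperature,
            )
            self.reservoir.compaction_listeners.append(
                self._remap_catalyst_beads
            )
            if populate:
                populate_region(
                    self.system, boundary, layout, reservoir_spec, library,
                    mp, rng_init, ip.temperature,
                )
        self.driver = MDDriver(
            self.system, boundary, mp, ip, seed=self.seed, layout=layout
        )
        self.step = 0
        self.series = TimeSeries()

    # -- internals ---------------------------------------------------------
    def _remap_catalyst_beads(self, new_index) -> None:
        """Keep catalyst bead references valid across bead compaction.

        Catalyst-referenced beads are always retained (they are tethered
        or part of an attached complex), but their indices shift when
        molecules are removed.
        """
        if new_index is None:
            return
        for cat in self.catalysts:
            for attr in ("bound_bead", "ring_c0", "ring_c1", "ring_c2"):
                v = getattr(cat, attr)
                if v >= 0:
                    setattr(cat, attr, int(new_index[v]))

    def _process_pending_conversions(self) -> None:
        sys_ = self.system
        if not sys_.pending_fene:
            return
        existing = {frozenset((i, j)) for i, j, _ in sys_.bonds}
        keep = []
        for i, j in sys_.pending_fene:
            if frozenset((i, j)) not in existing:
                continue  # bond was consumed by a later reaction
            d = sys_.pos[i] - sys_.pos[j]
            for dim in range(3):
                if self.boundary.pbc[dim]:
                    d[dim] -= self.boundary.box[dim] * np.rint(
                        d[dim] / self.boundary.box[dim]
                    )
            if np.linalg.norm(d) < self.rp.fene_convert_max:
                sys_.convert_bond(i, j, 0)
            else:
                keep.append((i, j))
        sys_.pending_fene = keep

    def _refresh_capture_flags(self) -> None:
        """Re-derive the per-bead inside-capture flags against the
        currently accepting sites.

        Binding is entry-triggered; after any reaction event the beads
        already sitting inside an accepting sphere (e.g. a freshly
        released chain end at the catalyst) must leave and re-enter
        before they can trigger another collision.
        """
        sys_ = self.system
        if not self.reactions_on or sys_.n_beads == 0:
            return
        sys_.in_capture[:] = 0
        acc = site_accept_array(self.catalysts, len(self.layout.site_pos))
        sites = self.layout.site_pos[np.flatnonzero(acc)]
        ri = sys_.reactive_index_array
        if len(sites) == 0 or len(ri) == 0:
            return
        d = sys_.pos[ri][:, None, :] - sites[None, :, :]
        for dim in range(3):
            if self.boundary.pbc[dim]:
                d[:, :, dim] -= self.boundary.box[dim] * np.rint(
                    d[:, :, dim] / self.boundary.box[dim]
                )
        inside = (d**2).sum(axis=2) < self.rp.capture_radius**2
        sys_.in_capture[ri[inside.any(axis=1)]] = 1

    def _due_breakups(self) -> None:
        t = self.system.time
        fired = False
        for cat in self.catalysts:
            if cat.has_ring and cat.breakup_time <= t:
                direction = choose_direction(self.rp, self.rng_react)
                apply_breakup(
                    self.system, self.catalysts, cat, direction, t,
                    self.ledger, boundary=self.boundary,
                    convert_max=self.rp.fene_convert_max,
                )
                fired = True
        self._process_pending_conversions()
        if fired:
            self._refresh_capture_flags()

    def _next_breakup_step(self) -> int:
        nxt = np.inf
        for cat in self.catalysts:
            if cat.has_ring:
                nxt = min(nxt, cat.breakup_time)
        if not np.isfinite(nxt):
            return 1 << 62
        remaining = max(0.0, nxt - self.system.time)
        return self.step + max(1, int(np.ceil(remaining / self.ip.dt)))

    def _sample(self, observers) -> None:
        sys_ = self.system
        self.series.time.append(sys_.time)
        self.series.kinetic_temperature.append(
            float(np.mean(sys_.vel**2)) if sys_.n_beads else 0.0
        )
        self.series.n_beads.append(sys_.n_beads)
        if self.reservoir is not None:
            # report by centre of mass: whole-molecule containment (the
            # exchange-move rule) undercounts at the coupling boundary
            from .geometry import coupled_mask
            from .system import MOL_SUBSTRATE

            count = 0
            for m in sys_.molecules(MOL_SUBSTRATE):
                com = sys_.pos[sys_.mol_id == m].mean(axis=0)
                if coupled_mask(com[None, :], self.boundary, self.layout)[0]:
                    count += 1
            self.series.n_substrates_coupled.append(count)
        else:
            self.series.n_substrates_coupled.append(0)
        for obs in observers:
            obs(sys_, self.boundary)

    # -- main loop ---------------------------------------------------------
    def run(
        self,
        n_steps: int,
        sample_interval: int = 0,
        observers: list | None = None,
        gcmc_on: bool = True,
    ) -> None:
        """Advance ``n_steps`` MD steps with all couplings active."""
        observers = observers or []
        end = self.step + n_steps
        gcmc_every = (
            self.reservoir.spec.sweep_interval
            if (self.reservoir is not None and gcmc_on)
            else 0
        )

        def _next_multiple(now: int, every: int) -> int:
            if every <= 0:
                return 1 << 62
            return ((now // every) + 1) * every

        while self.step < end:
            self._due_breakups()
            target = min(
                end,
                _next_multiple(self.step, gcmc_every),
                _next_multiple(self.step, sample_interval),
                self._next_breakup_step(),
            )
            block = target - self.step
            if block > 0:
                accept = (
                    site_accept_array(self.catalysts, len(self.layout.site_pos))
                    if self.reactions_on
                    else None
                )
                res = self.driver.run(
                    block,
                    check_reactions=self.reactions_on,
                    site_accept=accept,
                    capture_radius=self.rp.capture_radius,
                )
                self.step += res.steps_done
                if res.status == 1:
                    attempt_binding(
                        self.system,
                        self.catalysts,
                        res.site,
                        res.bead,
                        self.rp,
                        self.rng_react,
                        self.system.time,
                        self.ledger,
                        boundary=self.boundary,
                    )
                    self._refresh_capture_flags()
                    continue
            self._due_breakups()
            if gcmc_every and self.step % gcmc_every == 0:
                self.reservoir.sweep(self.system)
            if sample_interval and self.step % sample_interval == 0:
                self._sample(observers)

    # -- results -----------------------------------------------------------
    def mean_coupled_density_nm3(self, discard_fraction: float = 0.3) -> float:
        """Time-averaged substrate density in the coupled volume (nm^-3)."""
        from .units import UNITS

        counts = np.asarray(self.series.n_substrates_coupled, dtype=float)
        if len(counts) == 0:
            raise ValueError("no samples recorded")
        counts = counts[int(len(counts) * discard_fraction):]
        rho_red = counts.mean() / self.reservoir.volume
        return UNITS.density_to_per_nm3(rho_red)
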