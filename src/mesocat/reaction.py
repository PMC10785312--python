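"""Collision-triggered metathesis event engine.

The catalytic cycle mimics olefin metathesis at a two-site catalyst.  In
the resting state one site holds a single bead (the carbene carbon, C0 --
initially an artificial "cap" bead) or the end bead of an attached chain.
When a labeled olefin bead (C1) enters the capture sphere of the free
site, a bond trial fires: with probability ``P_bond`` the metal binds C1
and the former carbene partner C0 bonds to C1's labeled pair partner C2,
closing the transient 4-membered metallacycle
``C0 - metal - C1 - C2 - C0``.  The two new bonds are harmonic (they can
be created at separations where a FENE bond would diverge).  The ring
breaks open at rate ``1/tau_break``, either forward (the C0/C2 pair
leaves, C1 stays on the metal) or backward (exact inverse of the
binding).  A surviving C0-C2 bond is converted to a regular FENE chain
bond on release.

Released molecules are classified from their bond topology and lineage
tags: a cycle is a ring-closing (RC) product; an open chain containing
the backbones of at least two substrates is a polymerization (P) product;
a two-bead fragment is the ethylene-analog byproduct; an open chain that
is still a single substrate backbone (possibly with an exchanged end
carbon) is an unproductive chain transfer and is returned to the
substrate pool.  Selectivity uses only RC and P counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CatalystLayout
from .system import (
    BOND_FENE,
    BOND_HARMONIC,
    CAP_LINEAGE,
    MOL_BYPRODUCT,
    MOL_P,
    MOL_RC,
    MOL_SUBSTRATE,
    System,
)

#: Molecule kind for anything currently bonded to a catalyst.
MOL_ATTACHED = "attached"


class TopologyCorruptionError(RuntimeError):
    """The bond graph around a catalyst is not in the expected state."""


@dataclass(frozen=True)
class ReactionParams:
    """Parameters of the reaction model (reduced units).

    ``p_bond`` is the per-collision bond acceptance probability (the
    accelerated limit is 1).  ``tau_break`` is the mean lifetime of the
    4-ring.  ``capture_radius`` is the site capture sphere radius.
    ``forward_prob`` picks the forward (productive) ring-opening branch.
    """

    p_bond: float = 1.0
    tau_break: float = 10.0
    capture_radius: float = 1.0
    forward_prob: float = 0.5
    products_reactive: bool = True
    #: minimum metallacycle lifetime before breakup, so the freshly formed
    #: harmonic bonds can relax toward their rest length (reduced time)
    min_ring_lifetime: float = 1.0
    #: a surviving C0-C2 bond converts from harmonic to FENE only below
    #: this length (deferred otherwise; FENE diverges at r_max)
    fene_convert_max: float = 1.35
    #: safety bound on the C0-C2 separation at binding; effectively
    #: unlimited by default -- the force-capped harmonic bond makes
    #: formation at any collision geometry numerically safe, and a finite
    #: bound would suppress outer-bead-first collisions (the productive
    #: channels, whose C2 sits deeper) relative to inner-bead-first ones
    bind_max_dist: float = np.inf

    def __post_init__(self):
        if not 0.0 <= self.p_bond <= 1.0:
            raise ValueError("p_bond must be a probability")
        if self.tau_break <= 0:
            raise ValueError("tau_break must be positive")
        if not 0.0 <= self.forward_prob <= 1.0:
            raise ValueError("forward_prob must be a probability")


def draw_breakup_time(rp: ReactionParams, rng: np.random.Generator) -> float:
    """Exponential metallacycle lifetime with mean ``tau_break``."""
    return float(rng.exponential(rp.tau_break))


@dataclass
class Catalyst:
    """State of one fixed catalyst (sites are global site indices)."""

    index: int
    sites: tuple[int, int]
    bound_site: int = -1  # site holding the resting carbene
    bound_bead: int = -1
    # transient 4-ring bookkeeping
    ring_c0: int = -1
    ring_c1: int = -1
    ring_c2: int = -1
    ring_site_c1: int = -1
    breakup_time: float = np.inf

    @property
    def has_ring(self) -> bool:
        return self.ring_c1 >= 0

    @property
    def free_site(self) -> int:
        """The accepting site in the resting state (-1 mid-cycle)."""
        if self.has_ring or self.bound_site < 0:
            return -1
        a, b = self.sites
        return b if self.bound_site == a else a


@dataclass
class ReactionLedger:
    """Event log and running product counters."""

    events: list = field(default_factory=list)
    n_rc: int = 0
    n_p: int = 0
    n_byproduct: int = 0
    n_transfer: int = 0

    def record(
        self,
        time: float,
        catalyst: int,
        kind: str,
        direction: str = "",
        released_size: int = 0,
        released_lineages: int = 0,
        classification: str = "",
    ) -> None:
        self.events.append(
            (time, catalyst, kind, direction, released_size, released_lineages,
             classification)
        )
        if classification == "rc":
            self.n_rc += 1
        elif classification == "p":
            self.n_p += 1
        elif classification == "byproduct":
            self.n_byproduct += 1
        elif classification == "transfer":
            self.n_transfer += 1

    @property
    def n_productive(self) -> int:
        return self.n_rc + self.n_p

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events,
            columns=[
                "time",
                "catalyst",
                "event",
                "direction",
                "released_size",
                "released_lineages",
                "classification",
            ],
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> "ReactionLedger":
        df = pd.read_csv(path, sep="\t")
        led = ReactionLedger()
        for row in df.itertuples(index=False):
            led.record(
                row.time,
                row.catalyst,
                row.event,
                row.direction if isinstance(row.direction, str) else "",
                int(row.released_size),
                int(row.released_lineages),
                row.classification if isinstance(row.classification, str) else "",
            )
        return led


def initialize_catalysts(
    system: System,
    layout: CatalystLayout,
    rng: np.random.Generator,
    temperature: float = 1.0,
    tether_r0: float = 0.97,
) -> list[Catalyst]:
    """Put every catalyst into its resting state with a cap bead on site 0.

    The cap bead is label-flagged, carries the cap lineage and sits at the
    tether rest length outward of its site (away from the core centre).
    """
    catalysts = []
    for c in range(layout.n_catalysts):
        s0, s1 = 2 * c, 2 * c + 1
        site = layout.site_pos[s0]
        outward = site - layout.core_pos[c]
        outward = outward / np.linalg.norm(outward)
        bead_pos = site + tether_r0 * outward
        vel = rng.normal(scale=np.sqrt(temperature), size=(1, 3))
        mol = system.add_molecule(
            bead_pos[None, :],
            vel,
            labeled=np.array([True]),
            kind=MOL_ATTACHED,
            lineage=CAP_LINEAGE,
        )
        bead = int(system.beads_of(mol)[0])
        system.tethers[s0] = bead
        system.invalidate()
        catalysts.append(Catalyst(index=c, sites=(s0, s1), bound_site=s0,
                                  bound_bead=bead))
    return catalysts


def site_accept_array(catalysts: list[Catalyst], n_sites: int) -> np.ndarray:
    """Per-site accepting flags for the collision scan."""
    acc = np.zeros(n_sites, dtype=np.uint8)
    for cat in catalysts:
        s = cat.free_site
        if s >= 0:
            acc[s] = 1
    return acc


def classify_release(system: System, component: set[int]) -> str:
    """Topological classification of a fully detached component.

    Rules, in order: cyclic -> ``rc``; exactly two beads -> ``byproduct``
    (the ethylene analog, whatever its lineages); at least two substrate
    lineages each contributing two or more beads -> ``p``; otherwise the
    molecule is still a single substrate backbone (chain transfer /
    cap exchange) -> ``transfer``.
    """
    tethered = set(system.tethers.values())
    if component & tethered:
        raise ValueError("component is still bonded to a catalyst")
    if system.component_has_cycle(component):
        return "rc"
    if len(component) == 2:
        return "byproduct"
    counts: dict[int, int] = {}
    for b in component:
        lin = int(system.lineage[b])
        if lin != CAP_LINEAGE:
            counts[lin] = counts.get(lin, 0) + 1
    backbones = sum(1 for v in counts.values() if v >= 2)
    if backbones >= 2:
        return "p"
    return "transfer"


_KIND_FOR = {"rc": MOL_RC, "p": MOL_P, "byproduct": MOL_BYPRODUCT,
             "transfer": MOL_SUBSTRATE}


def _relabel_component(system: System, component: set[int], kind: str) -> int:
    """Assign a fresh molecule id and kind to a component."""
    mol = system.next_mol_id
    system.next_mol_id += 1
    idx = np.array(sorted(component), dtype=np.int64)
    old = set(int(m) for m in system.mol_id[idx])
    system.mol_id[idx] = mol
    for m in old:
        if not np.any(system.mol_id == m):
            system.mol_kind.pop(m, None)
    system.mol_kind[mol] = kind
    system.invalidate()
    return mol


def attempt_binding(
    system: System,
    catalysts: list[Catalyst],
    site: int,
    bead: int,
    rp: ReactionParams,
    rng: np.random.Generator,
    time: float,
    ledger: ReactionLedger,
    boundary=None,
) -> bool:
    """Resolve a collision between a reactive bead and an accepting site.

    Returns True if the metallacycle was formed.  The colliding bead
    becomes C1; its labeled pair partner becomes C2 and bonds to the
    resting carbene C0.
    """
    cat = catalysts[site // 2]
    if cat.free_site != site:
        return False
    c1 = int(bead)
    if c1 in set(system.tethers.values()) or not system.labeled[c1]:
        return False
    c2 = system.pair_partner(c1)
    if c2 is None:
        return False
    c0 = cat.bound_bead
    if c2 == c0 or c1 == c0:
        return False
    if _bond_length(system, c0, int(c2), boundary) > rp.bind_max_dist:
        return False
    if rp.p_bond < 1.0 and rng.random() >= rp.p_bond:
        return False
    # form the 4-ring: metal-C1 tether plus harmonic C0-C2
    system.tethers[site] = c1
    system.add_bond(c0, int(c2), BOND_HARMONIC)
    cat.ring_c0 = c0
    cat.ring_c1 = c1
    cat.ring_c2 = int(c2)
    cat.ring_site_c1 = site
    cat.breakup_time = time + rp.min_ring_lifetime + draw_breakup_time(rp, rng)
    merged = system.connected_component(c1)
    _relabel_component(system, merged, MOL_ATTACHED)
    ledger.record(time, cat.index, "bind")
    return True


def _bond_length(system: System, i: int, j: int, boundary) -> float:
    d = system.pos[i] - system.pos[j]
    if boundary is not None:
        for dim in range(3):
            if boundary.pbc[dim]:
                d[dim] -= boundary.box[dim] * np.rint(d[dim] / boundary.box[dim])
    return float(np.linalg.norm(d))


def apply_breakup(
    system: System,
    catalysts: list[Catalyst],
    cat: Catalyst,
    direction: str,
    time: float,
    ledger: ReactionLedger,
    boundary=None,
    convert_max: float = 1.35,
) -> list[tuple[int, str]]:
    """Open the 4-ring of ``cat``; returns [(mol_id, classification)] of
    released molecules.

    ``forward`` removes the metal-C0 tether and the C1-C2 chain bond and
    converts the surviving C0-C2 bond to FENE; ``backward`` removes the
    metal-C1 tether and the C0-C2 bond, restoring the pre-binding graph
    exactly.
    """
    if not cat.has_ring:
        raise TopologyCorruptionError("breakup requested without a 4-ring")
    c0, c1, c2 = cat.ring_c0, cat.ring_c1, cat.ring_c2
    site_c0 = cat.bound_site
    site_c1 = cat.ring_site_c1
    released: list[tuple[int, str]] = []
    if direction == "forward":
        if system.tethers.get(site_c0) != c0:
            raise TopologyCorruptionError("missing metal-C0 tether")
        del system.tethers[site_c0]
        system.remove_bond(c1, c2)
        # the surviving C0-C2 bond becomes a regular chain bond; if it is
        # still stretched near the FENE divergence, the conversion is
        # deferred until it has relaxed
        if _bond_length(system, c0, c2, boundary) < convert_max:
            system.convert_bond(c0, c2, BOND_FENE)
        else:
            system.pending_fene.append((c0, c2))
        cat.bound_site = site_c1
        cat.bound_bead = c1
        # C1 keeps its label; refresh the attached complex
        comp_attached = system.connected_component(c1)
        _relabel_component(system, comp_attached, MOL_ATTACHED)
        comp_freed = system.connected_component(c0)
        tethered = set(system.tethers.values())
        if comp_freed & tethered:
            # still bonded to some other catalyst: stays attached
            _relabel_component(system, comp_freed, MOL_ATTACHED)
            ledger.record(time, cat.index, "break_forward", "forward")
        else:
            cls = classify_release(system, comp_freed)
            mol = _relabel_component(system, comp_freed, _KIND_FOR[cls])
            lineages = {
                int(system.lineage[b])
                for b in comp_freed
                if system.lineage[b] != CAP_LINEAGE
            }
            ledger.record(
                time, cat.index, "break_forward", "forward",
                released_size=len(comp_freed),
                released_lineages=len(lineages),
                classification=cls,
            )
            released.append((mol, cls))
    elif direction == "backward":
        if system.tethers.get(site_c1) != c1:
            raise TopologyCorruptionError("missing metal-C1 tether")
        del system.tethers[site_c1]
        system.remove_bond(c0, c2)
        comp_attached = system.connected_component(c0)
        _relabel_component(system, comp_attached, MOL_ATTACHED)
        comp_freed = system.connected_component(c1)
        tethered = set(system.tethers.values())
        if comp_freed & tethered:
            _relabel_component(system, comp_freed, MOL_ATTACHED)
        else:
            # the visiting molecule simply detaches; recover its kind from
            # its (restored) topology, without counting anything
            cls = classify_release(system, comp_freed)
            _relabel_component(system, comp_freed, _KIND_FOR[cls])
        ledger.record(time, cat.index, "break_backward", "backward")
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    cat.ring_c0 = cat.ring_c1 = cat.ring_c2 = -1
    cat.ring_site_c1 = -1
    cat.breakup_time = np.inf
    # a lone bead left on the metal acts as the new carbene cap: it no
    # longer belongs to any substrate backbone
    comp_bound = system.connected_component(cat.bound_bead)
    if len(comp_bound) == 1:
        system.lineage[cat.bound_bead] = CAP_LINEAGE
        system.invalidate()
    return released


def choose_direction(rp: ReactionParams, rng: np.random.Generator) -> str:
    return "forward" if rng.random() < rp.forward_prob else "backward"
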