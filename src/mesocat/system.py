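"""Mutable particle system: beads, bonds, molecules and lineage tags.

The system owns struct-of-arrays bead storage plus a bond list.  Chain
bonds come in two kinds, FENE (kind 0, the regular Kremer-Grest backbone
bond) and harmonic reaction bonds (kind 1, created during catalytic
events).  Angle triplets are not stored independently: they are
regenerated from the FENE bond graph (every pair of adjacent FENE bonds
contributes one bending term), which keeps the bending topology consistent
through bond surgery without separate bookkeeping.

Tethers (bead to fixed anchor springs) represent bonds to catalyst
"metal" sites and are owned here as well, keyed by catalyst site index.

Lineage tags record which inserted substrate molecule a bead originally
came from (cap beads carry the tag -1); they are what allows a released
product to be classified as ring-closed versus polymerized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Lineage tag of carbene cap beads (never counts as a substrate lineage).
CAP_LINEAGE = -1

BOND_FENE = 0
BOND_HARMONIC = 1

#: Molecule kinds. Substrates (and transfer-released chains, which are
#: chemically intact substrates with an exchanged end bead) are exchanged
#: with the reservoir; products are only ever removed.
MOL_SUBSTRATE = "substrate"
MOL_RC = "rc"
MOL_P = "p"
MOL_BYPRODUCT = "byproduct"
MOL_CAP = "cap"


@dataclass
class System:
    """Bead-spring system state (reduced units)."""

    pos: np.ndarray  # (N, 3) float64
    vel: np.ndarray  # (N, 3) float64
    mol_id: np.ndarray  # (N,) int64
    lineage: np.ndarray  # (N,) int64
    labeled: np.ndarray  # (N,) bool
    # 1 while a bead sits inside an accepting capture sphere; binding is
    # entry-triggered (fires on the outside -> inside transition only)
    in_capture: np.ndarray  # (N,) uint8
    bonds: list  # of (i, j, kind)
    mol_kind: dict  # mol_id -> kind string
    time: float = 0.0
    next_mol_id: int = 0
    next_lineage: int = 0
    # tethers: site index -> bead index
    tethers: dict = field(default_factory=dict)
    # harmonic reaction bonds awaiting conversion to FENE once relaxed
    pending_fene: list = field(default_factory=list)

    # cached kernel arrays
    _arrays_dirty: bool = True
    _bond_arr: np.ndarray | None = None
    _bond_kind_arr: np.ndarray | None = None
    _angle_arr: np.ndarray | None = None
    _tether_bead: np.ndarray | None = None
    _reactive_idx: np.ndarray | None = None

    @staticmethod
    def empty() -> "System":
        return System(
            pos=np.zeros((0, 3)),
            vel=np.zeros((0, 3)),
            mol_id=np.zeros(0, dtype=np.int64),
            lineage=np.zeros(0, dtype=np.int64),
            labeled=np.zeros(0, dtype=bool),
            in_capture=np.zeros(0, dtype=np.uint8),
            bonds=[],
            mol_kind={},
        )

    @property
    def n_beads(self) -> int:
        return len(self.pos)

    def invalidate(self) -> None:
        self._arrays_dirty = True

    # -- molecule management ----------------------------------------------
    def add_molecule(
        self,
        pos: np.ndarray,
        vel: np.ndarray,
        labeled: np.ndarray,
        kind: str = MOL_SUBSTRATE,
        lineage: int | None = None,
        bond_pairs: list | None = None,
    ) -> int:
        """Append a molecule; returns its molecule id.

        ``bond_pairs`` are (local_i, local_j, kind) within the molecule;
        by default a linear FENE chain.
        """
        n = len(pos)
        base = self.n_beads
        mol = self.next_mol_id
        self.next_mol_id += 1
        if lineage is None:
            lineage = self.next_lineage
            self.next_lineage += 1
        self.pos = np.vstack([self.pos, pos])
        self.vel = np.vstack([self.vel, vel])
        self.mol_id = np.concatenate([self.mol_id, np.full(n, mol, dtype=np.int64)])
        self.lineage = np.concatenate(
            [self.lineage, np.full(n, lineage, dtype=np.int64)]
        )
        self.labeled = np.concatenate([self.labeled, np.asarray(labeled, dtype=bool)])
        self.in_capture = np.concatenate(
            [self.in_capture, np.zeros(n, dtype=np.uint8)]
        )
        if bond_pairs is None:
            bond_pairs = [(i, i + 1, BOND_FENE) for i in range(n - 1)]
        for i, j, k in bond_pairs:
            self.bonds.append((base + i, base + j, k))
        self.mol_kind[mol] = kind
        self.invalidate()
        return mol

    def remove_molecules(self, mol_ids):
        """Delete whole molecules, compacting bead storage.

        Tethered molecules cannot be removed.  Bead indices shift; the
        tether map and pending conversions are remapped here, and the
        old-to-new index map is returned so callers can remap any
        external bead references (e.g. catalyst state).
        """
        doomed = set(int(m) for m in mol_ids)
        if not doomed:
            return None
        for site, bead in self.tethers.items():
            if int(self.mol_id[bead]) in doomed:
                raise ValueError("cannot remove a catalyst-bound molecule")
        keep = ~np.isin(self.mol_id, list(doomed))
        new_index = np.cumsum(keep) - 1
        self.pos = self.pos[keep]
        self.vel = self.vel[keep]
        self.mol_id = self.mol_id[keep]
        self.lineage = self.lineage[keep]
        self.labeled = self.labeled[keep]
        self.in_capture = self.in_capture[keep]
        self.bonds = [
            (int(new_index[i]), int(new_index[j]), k)
            for (i, j, k) in self.bonds
            if keep[i] and keep[j]
        ]
        self.tethers = {s: int(new_index[b]) for s, b in self.tethers.items()}
        self.pending_fene = [
            (int(new_index[i]), int(new_index[j]))
            for (i, j) in self.pending_fene
            if keep[i] and keep[j]
        ]
        for m in doomed:
            self.mol_kind.pop(m, None)
        self.invalidate()
        return new_index

    def beads_of(self, mol: int) -> np.ndarray:
        return np.flatnonzero(self.mol_id == mol)

    def molecules(self, kind: str | None = None) -> list[int]:
        if kind is None:
            return sorted(self.mol_kind)
        return sorted(m for m, k in self.mol_kind.items() if k == kind)

    # -- bond graph --------------------------------------------------------
    def adjacency(self) -> dict[int, list[tuple[int, int]]]:
        """Bead -> list of (neighbour, bond kind) over chain bonds."""
        adj: dict[int, list[tuple[int, int]]] = {}
        for i, j, k in self.bonds:
            adj.setdefault(i, []).append((j, k))
            adj.setdefault(j, []).append((i, k))
        return adj

    def remove_bond(self, i: int, j: int) -> None:
        for idx, (a, b, k) in enumerate(self.bonds):
            if (a == i and b == j) or (a == j and b == i):
                del self.bonds[idx]
                self.invalidate()
                return
        raise KeyError(f"no bond between beads {i} and {j}")

    def add_bond(self, i: int, j: int, kind: int) -> None:
        for a, b, _ in self.bonds:
            if (a == i and b == j) or (a == j and b == i):
                raise ValueError(f"duplicate bond ({i}, {j})")
        self.bonds.append((i, j, kind))
        self.invalidate()

    def convert_bond(self, i: int, j: int, kind: int) -> None:
        for idx, (a, b, k) in enumerate(self.bonds):
            if (a == i and b == j) or (a == j and b == i):
                self.bonds[idx] = (a, b, kind)
                self.invalidate()
                return
        raise KeyError(f"no bond between beads {i} and {j}")

    def connected_component(self, seed: int) -> set[int]:
        adj = self.adjacency()
        seen = {seed}
        stack = [seed]
        while stack:
            u = stack.pop()
            for v, _ in adj.get(u, []):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    def component_has_cycle(self, component: set[int]) -> bool:
        """Connected component contains a cycle iff edges >= nodes."""
        edges = sum(
            1 for i, j, _ in self.bonds if i in component and j in component
        )
        return edges >= len(component)

    # -- kernel views ------------------------------------------------------
    def _rebuild_arrays(self) -> None:
        nb = len(self.bonds)
        bond_arr = np.empty((nb, 2), dtype=np.int64)
        kind_arr = np.empty(nb, dtype=np.int64)
        for idx, (i, j, k) in enumerate(self.bonds):
            bond_arr[idx, 0] = i
            bond_arr[idx, 1] = j
            kind_arr[idx] = k
        # angles: every pair of FENE bonds sharing a bead
        fene_adj: dict[int, list[int]] = {}
        for i, j, k in self.bonds:
            if k == BOND_FENE:
                fene_adj.setdefault(i, []).append(j)
                fene_adj.setdefault(j, []).append(i)
        triplets = []
        for centre, neigh in fene_adj.items():
            if len(neigh) >= 2:
                ns = sorted(neigh)
                for a in range(len(ns)):
                    for b in range(a + 1, len(ns)):
                        triplets.append((ns[a], centre, ns[b]))
        angle_arr = (
            np.array(triplets, dtype=np.int64)
            if triplets
            else np.zeros((0, 3), dtype=np.int64)
        )
        tether_bead = np.array(
            [self.tethers[s] for s in sorted(self.tethers)], dtype=np.int64
        )
        # reaction-competent beads: labeled, untethered, with a labeled
        # untethered chain-bond partner (the would-be C2)
        tethered = set(self.tethers.values())
        adj = self.adjacency()
        reactive = []
        for i in np.flatnonzero(self.labeled):
            i = int(i)
            if i in tethered:
                continue
            for j, _ in adj.get(i, []):
                if self.labeled[j] and j not in tethered:
                    reactive.append(i)
                    break
        self._bond_arr = bond_arr
        self._bond_kind_arr = kind_arr
        self._angle_arr = angle_arr
        self._tether_bead = tether_bead
        self._reactive_idx = np.array(sorted(reactive), dtype=np.int64)
        self._arrays_dirty = False

    @property
    def bond_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self._arrays_dirty:
            self._rebuild_arrays()
        return self._bond_arr, self._bond_kind_arr

    @property
    def angle_array(self) -> np.ndarray:
        if self._arrays_dirty:
            self._rebuild_arrays()
        return self._angle_arr

    @property
    def tether_bead_array(self) -> np.ndarray:
        if self._arrays_dirty:
            self._rebuild_arrays()
        return self._tether_bead

    @property
    def reactive_index_array(self) -> np.ndarray:
        if self._arrays_dirty:
            self._rebuild_arrays()
        return self._reactive_idx

    def tether_anchor_array(self, site_pos: np.ndarray) -> np.ndarray:
        """Anchor positions matching :attr:`tether_bead_array` order."""
        if self._arrays_dirty:
            self._rebuild_arrays()
        keys = sorted(self.tethers)
        if not keys:
            return np.zeros((0, 3))
        return site_pos[np.array(keys, dtype=np.int64)]

    def pair_partner(self, c1: int) -> int | None:
        """The labeled, untethered chain-bond neighbour of a labeled bead."""
        tethered = set(self.tethers.values())
        adj = self.adjacency()
        best = None
        for j, _ in adj.get(c1, []):
            if self.labeled[j] and j not in tethered:
                if best is None:
                    best = j
                else:
                    # two labeled neighbours: take the spatially closer one
                    db = np.linalg.norm(self.pos[best] - self.pos[c1])
                    dj = np.linalg.norm(self.pos[j] - self.pos[c1])
                    if dj < db:
                        best = j
        return best


def build_linear_chain(
    n_monomers: int,
    bond_length: float = 0.97,
    origin=(0.0, 0.0, 0.0),
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Straight chain positions and the substrate label mask.

    The first two and last two beads are labeled as the olefin carbon
    pairs that can react at a catalyst.
    """
    if n_monomers < 1:
        raise ValueError("need at least one bead")
    pos = np.zeros((n_monomers, 3))
    pos[:, 0] = np.arange(n_monomers) * bond_length
    pos += np.asarray(origin, dtype=float)
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pos += rng.normal(scale=jitter, size=pos.shape)
    labeled = np.zeros(n_monomers, dtype=bool)
    labeled[:2] = True
    labeled[-2:] = True
    return pos, labeled
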