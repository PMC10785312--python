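"""Measured quantities: selectivity, hydrodynamic radius, local densities.

Physical outputs are reported in nm / nm^-3; selectivities are fractions
of productive events.  Frame-based observables (densities, end-to-end
distance) are written as accumulators so a running simulation can feed
them one frame at a time without storing trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Boundary
from .reaction import ReactionLedger
from .system import MOL_SUBSTRATE, System
from .units import UNITS


class UndefinedSelectivityError(RuntimeError):
    """No productive (RC or P) events recorded."""


@dataclass(frozen=True)
class SelectivityResult:
    """Ring-closing selectivity S_RC = N_RC / (N_RC + N_P)."""

    s_rc: float
    n_rc: int
    n_p: int
    std: float = float("nan")  # across replicas, if pooled

    @property
    def binomial_se(self) -> float:
        n = self.n_rc + self.n_p
        return float(np.sqrt(self.s_rc * (1.0 - self.s_rc) / n))


def selectivity(ledger: ReactionLedger) -> SelectivityResult:
    """Selectivity from one event ledger; byproducts and transfers are
    excluded from the normalization."""
    n = ledger.n_rc + ledger.n_p
    if n < 1:
        raise UndefinedSelectivityError("no productive events recorded")
    return SelectivityResult(s_rc=ledger.n_rc / n, n_rc=ledger.n_rc, n_p=ledger.n_p)


def pooled_selectivity(ledgers: list[ReactionLedger]) -> SelectivityResult:
    """Pool events over replicas; std is the across-replica spread."""
    n_rc = sum(l.n_rc for l in ledgers)
    n_p = sum(l.n_p for l in ledgers)
    if n_rc + n_p < 1:
        raise UndefinedSelectivityError("no productive events recorded")
    per = [
        l.n_rc / (l.n_rc + l.n_p) for l in ledgers if (l.n_rc + l.n_p) > 0
    ]
    std = float(np.std(per, ddof=1)) if len(per) > 1 else float("nan")
    return SelectivityResult(
        s_rc=n_rc / (n_rc + n_p), n_rc=n_rc, n_p=n_p, std=std
    )


@dataclass(frozen=True)
class RHResult:
    """Kirkwood (Doi-Edwards) hydrodynamic radius in nm."""

    r_h_nm: float
    se_nm: float
    n_conformers: int


def hydrodynamic_radius(conformers) -> RHResult:
    """Kirkwood-type hydrodynamic radius of a conformer ensemble.

    The inverse radius is the ensemble average of the inverse bead-bead
    distance over all distinct pairs,
    ``1/R_H = (1/(N(N-1))) sum_{i != j} <1/r_ij>`` -- i.e. R_H is the
    harmonic mean bead-bead distance.  (This pair-count normalization is
    the one that reproduces the oligomer values quoted in the
    literature for this model.)

    ``conformers`` is an (n_conf, N, 3) array in reduced units, or a
    :class:`~mesocat.gcmc.ConformerLibrary`.
    """
    pos = getattr(conformers, "positions", conformers)
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 3:
        raise ValueError("need an (n_conformers, N, 3) array")
    n_conf, n, _ = pos.shape
    if n < 2:
        raise ValueError("need at least two beads")
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(pos[:, iu] - pos[:, ju], axis=2)
    if np.any(d <= 0):
        raise FloatingPointError("coincident beads in a conformer")
    # per-conformer inverse-radius estimate (both (i,j) orderings)
    a = 2.0 * np.sum(1.0 / d, axis=1) / (n * (n - 1))
    mean_a = float(np.mean(a))
    se_a = float(np.std(a, ddof=1) / np.sqrt(n_conf)) if n_conf > 1 else 0.0
    r_h = 1.0 / mean_a
    return RHResult(
        r_h_nm=UNITS.to_nm(r_h),
        se_nm=UNITS.to_nm(se_a / mean_a**2),
        n_conformers=n_conf,
    )


@dataclass(frozen=True)
class DensityProbe:
    """Wall-adjacent window where reactant-end availability is measured.

    Centred at the reactive-site offset from the wall (0.7 nm) with +-
    0.3 nm margin, i.e. the slab (or annular shell) 0.4-1.0 nm from the
    wall.
    """

    center_nm: float = 0.7
    half_width_nm: float = 0.3

    @property
    def lo_nm(self) -> float:
        return self.center_nm - self.half_width_nm

    @property
    def hi_nm(self) -> float:
        return self.center_nm + self.half_width_nm


def probe_volume_nm3(probe: DensityProbe, boundary: Boundary) -> float:
    """Window volume in nm^3 for the geometry at hand."""
    lo, hi = probe.lo_nm, probe.hi_nm
    if boundary.kind == "flat_wall":
        ly = UNITS.to_nm(boundary.box[1])
        lz = UNITS.to_nm(boundary.box[2])
        return (hi - lo) * ly * lz
    if boundary.kind == "slit":
        # window at each of the two pore walls
        l = UNITS.to_nm(boundary.pore_length)
        ly = UNITS.to_nm(boundary.box[1])
        d = UNITS.to_nm(boundary.pore_size)
        if 2 * hi > d:
            raise ValueError("probe windows overlap in this slit")
        return 2.0 * (hi - lo) * l * ly
    if boundary.kind == "cylinder":
        r = UNITS.to_nm(boundary.pore_size)
        l = UNITS.to_nm(boundary.pore_length)
        if r <= hi:
            raise ValueError("probe window reaches past the pore axis")
        return np.pi * ((r - lo) ** 2 - (r - hi) ** 2) * l
    raise ValueError("density probe requires a walled geometry")


def substrate_end_beads(system: System) -> np.ndarray:
    """Terminal beads of intact substrate molecules.

    Terminal means the outermost (chain-degree-1) label-flagged bead of
    each end; beads of products and catalyst-attached molecules are
    excluded.
    """
    degree = np.zeros(system.n_beads, dtype=np.int64)
    for i, j, _ in system.bonds:
        degree[i] += 1
        degree[j] += 1
    sub = set(system.molecules(MOL_SUBSTRATE))
    out = [
        b
        for b in range(system.n_beads)
        if degree[b] == 1
        and system.labeled[b]
        and int(system.mol_id[b]) in sub
    ]
    return np.array(out, dtype=np.int64)


def wall_window_distance(system: System, boundary: Boundary,
                         beads: np.ndarray) -> np.ndarray:
    """Distance (nm) of the given beads from the relevant wall surface.

    For pores only beads inside the pore section count; others get inf.
    """
    p = system.pos[beads]
    if boundary.kind == "flat_wall":
        return UNITS.to_nm(p[:, 0])
    box = boundary.box
    x = p[:, 0] % box[0]
    inside = x <= boundary.pore_length
    if boundary.kind == "slit":
        z_lo, z_hi = boundary.wall_params[1], boundary.wall_params[2]
        d = np.minimum(p[:, 2] - z_lo, z_hi - p[:, 2])
    elif boundary.kind == "cylinder":
        yc, zc = boundary.wall_params[2], boundary.wall_params[3]
        rr = np.sqrt((p[:, 1] - yc) ** 2 + (p[:, 2] - zc) ** 2)
        d = boundary.pore_size - rr
    else:
        raise ValueError("wall distance requires a walled geometry")
    d = UNITS.to_nm(d)
    d[~inside] = np.inf
    return d


@dataclass
class EndDensityAccumulator:
    """Time-averaged substrate end-monomer density in the probe window.

    Counts terminal labeled beads per window volume (each intact
    substrate contributes two); far from any wall this reads twice the
    substrate molecule density.  (A molecule-equivalent convention --
    dividing by two -- is ruled out by consistency: the published
    *reacting* flat-wall value exceeds the equilibrium window density
    under that normalization, and reactions can only deplete.)
    """

    probe: DensityProbe = field(default_factory=DensityProbe)
    counts: list = field(default_factory=list)

    def add_frame(self, system: System, boundary: Boundary) -> int:
        ends = substrate_end_beads(system)
        if len(ends) == 0:
            self.counts.append(0)
            return 0
        d = wall_window_distance(system, boundary, ends)
        c = int(np.sum((d >= self.probe.lo_nm) & (d <= self.probe.hi_nm)))
        self.counts.append(c)
        return c

    def density_nm3(self, boundary: Boundary) -> float:
        """Mean terminal-bead density in the window (nm^-3)."""
        if not self.counts:
            raise ValueError("no frames accumulated")
        return float(np.mean(self.counts)) / probe_volume_nm3(
            self.probe, boundary
        )

    @property
    def n_frames(self) -> int:
        return len(self.counts)


@dataclass
class EndToEndAccumulator:
    """Mean end-to-end distance of intact substrates, in nm."""

    values: list = field(default_factory=list)

    def add_frame(self, system: System,
                  boundary: Boundary | None = None,
                  inside_pore_only: bool = False) -> None:
        for m in system.molecules(MOL_SUBSTRATE):
            beads = system.beads_of(m)
            degree: dict[int, int] = {}
            bset = set(int(b) for b in beads)
            for i, j, _ in system.bonds:
                if i in bset:
                    degree[i] = degree.get(i, 0) + 1
                if j in bset:
                    degree[j] = degree.get(j, 0) + 1
            termini = [b for b in bset if degree.get(b, 0) == 1]
            if len(termini) != 2:
                continue
            if inside_pore_only and boundary is not None:
                x = system.pos[list(bset), 0] % boundary.box[0]
                if not np.all(x <= boundary.pore_length):
                    continue
            r = np.linalg.norm(system.pos[termini[0]] - system.pos[termini[1]])
            self.values.append(r)

    def mean_nm(self) -> float:
        if not self.values:
            raise ValueError("no molecules accumulated")
        return UNITS.to_nm(float(np.mean(self.values)))


@dataclass
class AxialProfileAccumulator:
    """Substrate monomer density along the pore axis (nm^-3 per bin)."""

    n_bins: int = 20
    hist: np.ndarray | None = None
    n_frames: int = 0

    def add_frame(self, system: System, boundary: Boundary) -> None:
        if boundary.kind not in ("slit", "cylinder"):
            raise ValueError("axial profile requires a pore geometry")
        if self.hist is None:
            self.hist = np.zeros(self.n_bins)
        sub = set(system.molecules(MOL_SUBSTRATE))
        if sub:
            sel = np.isin(system.mol_id, list(sub))
            x = system.pos[sel, 0] % boundary.box[0]
            x = x[x <= boundary.pore_length]
            h, _ = np.histogram(x, bins=self.n_bins,
                                range=(0.0, boundary.pore_length))
            self.hist += h
        self.n_frames += 1

    def profile_nm3(self, boundary: Boundary) -> tuple[np.ndarray, np.ndarray]:
        """(bin centres nm, mean substrate monomer density nm^-3)."""
        if self.hist is None or self.n_frames == 0:
            raise ValueError("no frames accumulated")
        l = boundary.pore_length
        if boundary.kind == "slit":
            cross = boundary.box[1] * boundary.pore_size
        else:
            cross = np.pi * boundary.pore_size**2
        bin_vol = UNITS.volume_to_nm3(cross * l / self.n_bins)
        edges = np.linspace(0.0, UNITS.to_nm(l), self.n_bins + 1)
        centres = 0.5 * (edges[:-1] + edges[1:])
        return centres, self.hist / self.n_frames / bin_vol
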