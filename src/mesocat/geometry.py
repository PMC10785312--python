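"""Simulation geometries: bulk, planar wall, slit pore and cylindrical pore.

All walls are analytic (no explicit wall atoms): a bead interacts with the
nearest wall material through a purely repulsive WCA potential of its
distance to the material, with the same length and energy scale as the
bead-bead repulsion.  The slit and cylindrical pores are finite membranes
embedded in an open outside volume, so substrate has to diffuse in and out
through the pore openings; the membrane material has capped rims, so beads
cannot cross between inside and outside except through the openings.

Internally everything is in reduced units; constructors take nm, matching
the configuration format.

Catalysts are placed at fixed positions: at planar walls randomly with a
minimum separation, in cylindrical pores equally spaced along the axis
with a random azimuth.  Each catalyst is an impenetrable core sphere
carrying two reactive sites whose centres sit exactly ``d_cat`` from the
wall and ``1.3 sigma`` from each other, protruding just above the core
surface so the capture volume stays thermally accessible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import WCA_CUT_FACTOR, EPSILON_DEFAULT, PairParams, wca_energy
from .units import UNITS

#: Offset of the reactive-site centres from the wall, nm.
D_CAT_NM = 0.7

#: Catalyst surface density at the reactive-site location, nm^-2.
SIGMA_CAT_NM2 = 0.036

#: Minimum catalyst-catalyst separation, nm.
L_EX_NM = 2.5

#: Catalyst core radius, nm (comparable to the size of a real catalyst).
CORE_RADIUS_NM = 0.5

#: Half the separation of the two reactive sites, reduced units.
SITE_HALF_SEP = 0.65

#: How far the site centres protrude above the core surface (reduced
#: units).  The sites are small permeable spheres attached to the outside
#: of the impenetrable holder; anchoring their centres one site radius
#: above the surface keeps the capture volume thermally accessible
#: instead of buried in the holder's repulsion.
SITE_PROTRUSION = 0.5

#: Distance from a planar wall beyond which the reservoir coupling starts, nm.
COUPLE_DIST_NM = 9.0

#: Padding of the coupled region away from a pore entry, nm.
L_PAD_NM = 5.0


class GeometryError(ValueError):
    """Inconsistent or infeasible geometric specification."""


class EscapedParticleError(RuntimeError):
    """A bead ended up inside wall material."""


@dataclass(frozen=True)
class Boundary:
    """A simulation box with its boundary conditions (reduced units).

    ``wall_kind``/``wall_params`` use the encoding of
    :mod:`mesocat._kernels`.  ``pore_length`` is zero for bulk and flat
    geometries.
    """

    kind: str  # bulk | flat_wall | slit | cylinder
    box: np.ndarray  # (3,) reduced
    pbc: np.ndarray  # (3,) uint8
    wall_kind: int
    wall_params: np.ndarray  # (4,)
    pore_length: float = 0.0
    pore_size: float = 0.0  # slit width or cylinder radius, reduced
    couple_dist: float = 0.0
    pad: float = 0.0

    # -- constructors ------------------------------------------------------
    @staticmethod
    def bulk(L_nm: float | tuple = 10.0, couple_dist_nm: float = COUPLE_DIST_NM) -> "Boundary":
        L = np.atleast_1d(np.asarray(L_nm, dtype=float))
        if L.size == 1:
            L = np.repeat(L, 3)
        box = UNITS.from_nm(L)
        return Boundary(
            kind="bulk",
            box=box,
            pbc=np.ones(3, dtype=np.uint8),
            wall_kind=0,
            wall_params=np.zeros(4),
            couple_dist=UNITS.from_nm(couple_dist_nm),
        )

    @staticmethod
    def open_box(L_nm: float = 10.0) -> "Boundary":
        """Unbounded space (no walls, no periodicity); for single-molecule
        sampling where images are irrelevant."""
        L = np.repeat(float(L_nm), 3)
        return Boundary(
            kind="bulk",
            box=UNITS.from_nm(L),
            pbc=np.zeros(3, dtype=np.uint8),
            wall_kind=0,
            wall_params=np.zeros(4),
        )

    @staticmethod
    def flat_wall(
        Lx_nm: float = 34.2,
        Ly_nm: float = 10.21,
        Lz_nm: float = 10.21,
        couple_dist_nm: float = COUPLE_DIST_NM,
    ) -> "Boundary":
        box = UNITS.from_nm(np.array([Lx_nm, Ly_nm, Lz_nm]))
        return Boundary(
            kind="flat_wall",
            box=box,
            pbc=np.array([0, 1, 1], dtype=np.uint8),
            wall_kind=1,
            wall_params=np.zeros(4),
            couple_dist=UNITS.from_nm(couple_dist_nm),
        )

    @staticmethod
    def slit(
        d_slit_nm: float,
        l_nm: float = 35.8,
        Lout_nm: float = 34.2,
        Ly_nm: float = 10.21,
        Lz_nm: float = 10.21,
        pad_nm: float = L_PAD_NM,
    ) -> "Boundary":
        if d_slit_nm <= 0 or d_slit_nm >= Lz_nm:
            raise GeometryError("slit width must lie in (0, Lz)")
        box = UNITS.from_nm(np.array([l_nm + Lout_nm, Ly_nm, Lz_nm]))
        d = UNITS.from_nm(d_slit_nm)
        z_lo = 0.5 * (box[2] - d)
        wall_p = np.array([UNITS.from_nm(l_nm), z_lo, z_lo + d, 0.0])
        return Boundary(
            kind="slit",
            box=box,
            pbc=np.ones(3, dtype=np.uint8),
            wall_kind=2,
            wall_params=wall_p,
            pore_length=UNITS.from_nm(l_nm),
            pore_size=d,
            pad=UNITS.from_nm(pad_nm),
        )

    @staticmethod
    def cylinder(
        r_nm: float,
        l_nm: float = 35.8,
        Lout_nm: float = 34.2,
        Ly_nm: float = 10.21,
        Lz_nm: float = 10.21,
        pad_nm: float = L_PAD_NM,
    ) -> "Boundary":
        if 2 * r_nm >= min(Ly_nm, Lz_nm):
            raise GeometryError("pore diameter must be smaller than the box")
        if r_nm <= D_CAT_NM:
            raise GeometryError("pore radius must exceed the site offset d_cat")
        box = UNITS.from_nm(np.array([l_nm + Lout_nm, Ly_nm, Lz_nm]))
        wall_p = np.array(
            [UNITS.from_nm(l_nm), UNITS.from_nm(r_nm), 0.5 * box[1], 0.5 * box[2]]
        )
        return Boundary(
            kind="cylinder",
            box=box,
            pbc=np.ones(3, dtype=np.uint8),
            wall_kind=3,
            wall_params=wall_p,
            pore_length=UNITS.from_nm(l_nm),
            pore_size=UNITS.from_nm(r_nm),
            pad=UNITS.from_nm(pad_nm),
        )

    # -- queries -----------------------------------------------------------
    def wall_distance(self, position) -> float:
        """Distance (reduced) from a point to the nearest wall material."""
        p = np.asarray(position, dtype=float)
        d, _, _, _ = _kernels._wall_dist(
            p[0], p[1], p[2], self.wall_kind, self.wall_params, self.box
        )
        return float(d)

    @property
    def volume(self) -> float:
        """Accessible box volume (reduced); membrane material excluded."""
        v = float(np.prod(self.box))
        if self.kind == "slit":
            l = self.pore_length
            v -= l * self.box[1] * (self.box[2] - self.pore_size)
        elif self.kind == "cylinder":
            l = self.pore_length
            v -= l * (self.box[1] * self.box[2] - np.pi * self.pore_size**2)
        return v


def wall_energy(position, boundary: Boundary, p: PairParams | None = None) -> float:
    """Repulsive WCA wall energy of a bead at ``position`` (reduced units).

    Raises :class:`EscapedParticleError` for a bead inside wall material.
    """
    if boundary.wall_kind == 0:
        return 0.0
    if p is None:
        p = PairParams()
    d = boundary.wall_distance(position)
    if d <= 0.0:
        raise EscapedParticleError(f"bead at negative wall distance {d:.4g}")
    if d >= p.cutoff:
        return 0.0
    return float(wca_energy(d, p))


@dataclass
class CatalystLayout:
    """Realized catalyst positions (reduced units).

    ``site_pos`` has shape (2 * n_cat, 3); sites ``2c`` and ``2c + 1``
    belong to catalyst ``c``.  Catalysts are immobile for the entire run.
    """

    core_pos: np.ndarray
    site_pos: np.ndarray
    core_radius: float = field(default_factory=lambda: UNITS.from_nm(CORE_RADIUS_NM))

    @property
    def n_catalysts(self) -> int:
        return len(self.core_pos)

    @staticmethod
    def empty() -> "CatalystLayout":
        return CatalystLayout(
            core_pos=np.zeros((0, 3)), site_pos=np.zeros((0, 3))
        )


def catalyst_count(boundary: Boundary, sigma_cat_nm2: float = SIGMA_CAT_NM2) -> int:
    """Number of catalysts from the surface density rule ``floor(sigma A)``.

    The reference area is a single wall for flat and slit geometries and
    the cylindrical shell through the reactive sites (radius
    ``r - d_cat``) for pores, so that the density is measured where the
    active sites actually sit.
    """
    if sigma_cat_nm2 < 0:
        raise GeometryError("sigma_cat must be non-negative")
    if boundary.kind == "flat_wall":
        area = UNITS.to_nm(boundary.box[1]) * UNITS.to_nm(boundary.box[2])
    elif boundary.kind == "slit":
        area = UNITS.to_nm(boundary.pore_length) * UNITS.to_nm(boundary.box[1])
    elif boundary.kind == "cylinder":
        r_eff = UNITS.to_nm(boundary.pore_size) - D_CAT_NM
        if r_eff <= 0:
            raise GeometryError("cylinder radius must exceed d_cat")
        area = 2.0 * np.pi * r_eff * UNITS.to_nm(boundary.pore_length)
    else:
        raise GeometryError("catalyst_count requires a walled geometry")
    return int(np.floor(sigma_cat_nm2 * area))


def _site_geometry(base: np.ndarray, normal: np.ndarray, axis: np.ndarray,
                   core_radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Core centre and the two site centres for a wall anchor point.

    ``base`` is the point on the wall, ``normal`` the inward unit normal,
    ``axis`` the unit direction of the site pair (perpendicular to
    ``normal``).  Sites sit at ``d_cat`` from the wall, ``1.3 sigma``
    apart, protruding one site radius above the core surface; the core
    centre is displaced further from the wall accordingly.
    """
    d_cat = UNITS.from_nm(D_CAT_NM)
    delta = np.sqrt((core_radius + SITE_PROTRUSION) ** 2 - SITE_HALF_SEP**2)
    centre = base + (d_cat + delta) * normal
    s1 = base + d_cat * normal + SITE_HALF_SEP * axis
    s2 = base + d_cat * normal - SITE_HALF_SEP * axis
    return centre, np.stack([s1, s2])


def place_catalysts_planar(
    n: int,
    boundary: Boundary,
    rng: np.random.Generator,
    l_ex_nm: float = L_EX_NM,
    core_radius_nm: float = CORE_RADIUS_NM,
    max_rounds: int = 10_000,
) -> CatalystLayout:
    """Randomly place ``n`` catalysts on the planar wall(s).

    For ``flat_wall`` all catalysts go on the x = 0 wall; for ``slit``
    they alternate between the two pore walls.  All pairwise (periodic,
    3D) core distances are at least ``l_ex``.
    """
    if boundary.kind not in ("flat_wall", "slit"):
        raise GeometryError("planar placement requires flat_wall or slit")
    core_radius = UNITS.from_nm(core_radius_nm)
    l_ex = UNITS.from_nm(l_ex_nm)
    box = boundary.box
    if boundary.kind == "flat_wall":
        area = box[1] * box[2]
    else:
        area = boundary.pore_length * box[1]
    if n * np.pi * (l_ex / 2.0) ** 2 > 4.0 * area:
        raise GeometryError(f"cannot pack {n} catalysts at l_ex = {l_ex_nm} nm")
    cores: list[np.ndarray] = []
    sites: list[np.ndarray] = []
    for c in range(n):
        for attempt in range(max_rounds):
            if boundary.kind == "flat_wall":
                base = np.array(
                    [0.0, rng.uniform(0, box[1]), rng.uniform(0, box[2])]
                )
                normal = np.array([1.0, 0.0, 0.0])
                phi = rng.uniform(0, 2 * np.pi)
                axis = np.array([0.0, np.cos(phi), np.sin(phi)])
            else:
                x = rng.uniform(0, boundary.pore_length)
                y = rng.uniform(0, box[1])
                if c % 2 == 0:
                    base = np.array([x, y, boundary.wall_params[1]])
                    normal = np.array([0.0, 0.0, 1.0])
                else:
                    base = np.array([x, y, boundary.wall_params[2]])
                    normal = np.array([0.0, 0.0, -1.0])
                phi = rng.uniform(0, 2 * np.pi)
                axis = np.array([np.cos(phi), np.sin(phi), 0.0])
            centre, spos = _site_geometry(base, normal, axis, core_radius)
            ok = True
            for other in cores:
                d = centre - other
                for dim in range(3):
                    if boundary.pbc[dim]:
                        d[dim] -= box[dim] * np.rint(d[dim] / box[dim])
                if np.dot(d, d) < l_ex**2:
                    ok = False
                    break
            if ok:
                cores.append(centre)
                sites.append(spos)
                break
        else:
            raise GeometryError(
                f"failed to place catalyst {c + 1}/{n} after {max_rounds} rounds"
            )
    if n == 0:
        return CatalystLayout.empty()
    return CatalystLayout(
        core_pos=np.array(cores),
        site_pos=np.concatenate(sites),
        core_radius=core_radius,
    )


def place_catalysts_cylinder(
    n: int,
    boundary: Boundary,
    rng: np.random.Generator,
    core_radius_nm: float = CORE_RADIUS_NM,
) -> CatalystLayout:
    """Place ``n`` catalysts in a cylindrical pore.

    Axial coordinates are equally spaced (offset by half a spacing);
    azimuths are independent and uniform.  The site pair is oriented along
    the pore axis so both sites sit exactly ``d_cat`` from the curved
    wall.
    """
    if boundary.kind != "cylinder":
        raise GeometryError("cylinder placement requires a cylinder boundary")
    if n < 1:
        raise GeometryError("need at least one catalyst")
    core_radius = UNITS.from_nm(core_radius_nm)
    d_cat = UNITS.from_nm(D_CAT_NM)
    r_pore = boundary.pore_size
    if r_pore <= d_cat:
        raise GeometryError("pore radius must exceed d_cat")
    l = boundary.pore_length
    yc, zc = boundary.wall_params[2], boundary.wall_params[3]
    delta = np.sqrt((core_radius + SITE_PROTRUSION) ** 2 - SITE_HALF_SEP**2)
    cores = np.empty((n, 3))
    sites = np.empty((2 * n, 3))
    for c in range(n):
        x = (c + 0.5) * l / n
        theta = rng.uniform(0, 2 * np.pi)
        rho_hat = np.array([0.0, np.cos(theta), np.sin(theta)])
        site_r = r_pore - d_cat
        centre_r = site_r - delta
        cores[c] = np.array([x, yc, zc]) + centre_r * rho_hat
        sites[2 * c] = np.array([x + SITE_HALF_SEP, yc, zc]) + site_r * rho_hat
        sites[2 * c + 1] = np.array([x - SITE_HALF_SEP, yc, zc]) + site_r * rho_hat
    return CatalystLayout(core_pos=cores, site_pos=sites, core_radius=core_radius)


def place_catalysts_bulk(
    n: int,
    boundary: Boundary,
    rng: np.random.Generator,
    core_radius_nm: float = CORE_RADIUS_NM,
    min_sep_nm: float = 6.0,
    max_rounds: int = 10_000,
) -> CatalystLayout:
    """Fixed catalysts in a periodic bulk box, far from each other.

    Positions are uniform with a pairwise minimum separation chosen so
    that chains attached to different catalysts can never interact
    (default 6 nm, several chain extents); orientations are uniformly
    random.  The uncoupled buffer spheres around different catalysts may
    overlap; the coupled volume accounts for that.
    """
    if boundary.kind != "bulk":
        raise GeometryError("bulk placement requires a bulk boundary")
    if n < 1:
        raise GeometryError("need at least one catalyst")
    core_radius = UNITS.from_nm(core_radius_nm)
    d_cat = UNITS.from_nm(D_CAT_NM)
    delta = np.sqrt((core_radius + SITE_PROTRUSION) ** 2 - SITE_HALF_SEP**2)
    min_sep = UNITS.from_nm(min_sep_nm)
    box = boundary.box
    cores: list[np.ndarray] = []
    sites: list[np.ndarray] = []
    for c in range(n):
        for _ in range(max_rounds):
            centre = rng.uniform(0, 1, 3) * box
            ok = True
            for other in cores:
                d = centre - other
                d -= box * np.rint(d / box)
                if np.dot(d, d) < min_sep**2:
                    ok = False
                    break
            if ok:
                break
        else:
            raise GeometryError(
                f"cannot place {n} well-separated catalysts in this box"
            )
        # random orthonormal frame: normal (site direction) + pair axis
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        t = rng.normal(size=3)
        t -= np.dot(t, normal) * normal
        axis = t / np.linalg.norm(t)
        base = centre - (d_cat + delta) * normal  # virtual "wall" anchor
        cc, spos = _site_geometry(base, normal, axis, core_radius)
        cores.append(cc)
        sites.append(spos)
    return CatalystLayout(
        core_pos=np.array(cores),
        site_pos=np.concatenate(sites),
        core_radius=core_radius,
    )


def place_catalysts(
    boundary: Boundary,
    rng: np.random.Generator,
    n: int | None = None,
    sigma_cat_nm2: float = SIGMA_CAT_NM2,
) -> CatalystLayout:
    """Place catalysts for any walled geometry (count from the density rule)."""
    if n is None:
        n = catalyst_count(boundary, sigma_cat_nm2)
    if boundary.kind == "cylinder":
        return place_catalysts_cylinder(n, boundary, rng)
    return place_catalysts_planar(n, boundary, rng)


def region_membership(
    position,
    boundary: Boundary,
    layout: CatalystLayout | None = None,
) -> str:
    """Classify a point as ``coupled``, ``buffer`` or ``catalyst_zone``.

    The coupled region is where grand-canonical exchange happens: beyond
    ``couple_dist`` from the wall (flat) or from every catalyst (bulk),
    or the outside volume minus the entry padding (pores).  The
    catalyst zone is the immediate neighbourhood of a catalyst core.
    """
    p = np.asarray(position, dtype=float)
    box = boundary.box
    if layout is not None and layout.n_catalysts:
        zone = layout.core_radius + WCA_CUT_FACTOR
        for core in layout.core_pos:
            d = p - core
            for dim in range(3):
                if boundary.pbc[dim]:
                    d[dim] -= box[dim] * np.rint(d[dim] / box[dim])
            if np.dot(d, d) < zone**2:
                return "catalyst_zone"
    if boundary.kind == "bulk":
        if layout is None or layout.n_catalysts == 0:
            return "coupled"
        for core in layout.core_pos:
            d = p - core
            for dim in range(3):
                if boundary.pbc[dim]:
                    d[dim] -= box[dim] * np.rint(d[dim] / box[dim])
            if np.dot(d, d) < boundary.couple_dist**2:
                return "buffer"
        return "coupled"
    if boundary.kind == "flat_wall":
        return "coupled" if p[0] >= boundary.couple_dist else "buffer"
    # pores: coupled only in the outside volume away from the entries
    x = p[0] % box[0]
    lo = boundary.pore_length + boundary.pad
    hi = box[0] - boundary.pad
    return "coupled" if lo <= x <= hi else "buffer"


def coupled_mask(
    positions: np.ndarray,
    boundary: Boundary,
    layout: CatalystLayout | None = None,
) -> np.ndarray:
    """Vectorized membership test: True where a point is in the coupled
    region (equivalent to ``region_membership(...) == 'coupled'`` because
    the catalyst zone never intersects the coupled volume)."""
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    box = boundary.box
    if boundary.kind == "bulk":
        mask = np.ones(len(p), dtype=bool)
        if layout is not None and layout.n_catalysts:
            for core in layout.core_pos:
                d = p - core
                for dim in range(3):
                    if boundary.pbc[dim]:
                        d[:, dim] -= box[dim] * np.rint(d[:, dim] / box[dim])
                mask &= np.einsum("ij,ij->i", d, d) >= boundary.couple_dist**2
        return mask
    if boundary.kind == "flat_wall":
        return p[:, 0] >= boundary.couple_dist
    x = p[:, 0] % box[0]
    lo = boundary.pore_length + boundary.pad
    hi = box[0] - boundary.pad
    return (x >= lo) & (x <= hi)


def coupled_volume(boundary: Boundary, layout: CatalystLayout | None = None) -> float:
    """Volume of the reservoir-coupled region (reduced units)."""
    box = boundary.box
    if boundary.kind == "bulk":
        v_box = float(np.prod(box))
        if layout is None or layout.n_catalysts == 0:
            return v_box
        if 2.0 * boundary.couple_dist <= float(np.min(box)) and (
            layout.n_catalysts == 1
        ):
            v = v_box - (4.0 / 3.0) * np.pi * boundary.couple_dist**3
        else:
            # buffer spheres may be clipped by the box or by each other:
            # deterministic Monte Carlo volume (relative error ~1e-3)
            rng = np.random.default_rng(np.random.SeedSequence([7, 7, 7]))
            pts = rng.uniform(0, 1, size=(400_000, 3)) * box
            v = v_box * float(np.mean(coupled_mask(pts, boundary, layout)))
        if v <= 0:
            raise GeometryError("coupled region is empty")
        return v
    if boundary.kind == "flat_wall":
        v = float((box[0] - boundary.couple_dist) * box[1] * box[2])
        if v <= 0:
            raise GeometryError("coupled region is empty")
        return v
    v = float((box[0] - boundary.pore_length - 2 * boundary.pad) * box[1] * box[2])
    if v <= 0:
        raise GeometryError("coupled region is empty")
    return v


def sample_coupled_point(
    boundary: Boundary,
    rng: np.random.Generator,
    layout: CatalystLayout | None = None,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Uniform random point in the coupled region (reduced units)."""
    box = boundary.box
    for _ in range(max_tries):
        if boundary.kind == "flat_wall":
            p = np.array(
                [
                    rng.uniform(boundary.couple_dist, box[0]),
                    rng.uniform(0, box[1]),
                    rng.uniform(0, box[2]),
                ]
            )
        elif boundary.kind in ("slit", "cylinder"):
            lo = boundary.pore_length + boundary.pad
            hi = box[0] - boundary.pad
            p = np.array(
                [
                    rng.uniform(lo, hi),
                    rng.uniform(0, box[1]),
                    rng.uniform(0, box[2]),
                ]
            )
        else:
            p = rng.uniform(0, 1, 3) * box
        if region_membership(p, boundary, layout) == "coupled":
            return p
    raise GeometryError("could not sample a point in the coupled region")
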