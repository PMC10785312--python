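"""Interaction parameters and closed-form potentials of the bead-spring model.

The substrate oligomers are Kremer-Grest chains: beads repel through a
purely repulsive, cut-and-shifted Lennard-Jones (WCA) potential and bonded
neighbours attract through a finitely extensible (FENE) spring.  Chain
rigidity enters through a harmonic bending potential with equilibrium angle
``pi`` (straight backbone).  Bonds created transiently during a catalytic
event are plain harmonic springs, because they can be formed at separations
where a FENE bond would already have diverged.

All functions here operate in reduced units (see :mod:`mesocat.units`) and
are scalar/array friendly; the heavily vectorised force kernels live in
:mod:`mesocat._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: WCA cutoff factor, the potential minimum of the underlying LJ: 2**(1/6).
WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)

#: Bead-bead (and bead-wall) repulsion strength in k_B T.
EPSILON_DEFAULT = 0.833

#: Standard Kremer-Grest FENE spring constant, in epsilon/sigma^2.
FENE_K_DEFAULT = 30.0

#: Standard Kremer-Grest FENE maximum extension, in sigma.
FENE_RMAX_DEFAULT = 1.5

#: Backbone bending stiffness (k_B T/rad^2) calibrated for the 22-mer.
K_ANGLE_22 = 5.09

#: Backbone bending stiffness (k_B T/rad^2) calibrated for the 29-mer.
K_ANGLE_29 = 4.32


def angle_stiffness_for(n_monomers: int) -> float:
    """Calibrated bending stiffness for the two supported chain lengths."""
    table = {22: K_ANGLE_22, 29: K_ANGLE_29}
    if n_monomers not in table:
        raise ValueError(
            f"no calibrated angle stiffness for N_m={n_monomers}; "
            "known chain lengths are 22 and 29"
        )
    return table[n_monomers]


@dataclass(frozen=True)
class PairParams:
    """WCA pair interaction parameters (reduced units)."""

    epsilon: float = EPSILON_DEFAULT
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def cutoff(self) -> float:
        """WCA cutoff, exactly 2^(1/6) sigma."""
        return WCA_CUT_FACTOR * self.sigma


@dataclass(frozen=True)
class FeneParams:
    """FENE bond parameters (reduced units)."""

    K: float = FENE_K_DEFAULT
    r_max: float = FENE_RMAX_DEFAULT

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r_max <= 0:
            raise ValueError("FENE K and r_max must be positive")


@dataclass(frozen=True)
class AngleParams:
    """Harmonic bending parameters; the equilibrium angle is fixed at pi."""

    K_angle: float
    phi0: float = np.pi

    def __post_init__(self) -> None:
        if self.K_angle < 0:
            raise ValueError("K_angle must be non-negative")


@dataclass(frozen=True)
class HarmonicBondParams:
    """Harmonic reaction-bond parameters (rest length r0, stiffness k)."""

    k: float = 100.0
    r0: float = 0.97


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin integrator parameters (reduced units)."""

    dt: float = 0.01
    gamma: float = 1.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


class DivergedBondError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension."""

    def __init__(self, i: int, j: int, r: float):
        super().__init__(f"FENE bond ({i}, {j}) diverged at r = {r:.4f} sigma")
        self.beads = (i, j)
        self.r = r


def wca_energy(r, p: PairParams = PairParams()):
    """WCA (cut-and-shifted LJ) pair energy at separation ``r``.

    Zero at and beyond ``2^(1/6) sigma``; continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    sr6 = (p.sigma / r) ** 6
    e = 4.0 * p.epsilon * (sr6 * sr6 - sr6) + p.epsilon
    return np.where(r < p.cutoff, e, 0.0)[()]


def fene_energy(r, p: FeneParams = FeneParams()):
    """FENE attractive bond energy; diverges at ``r_max``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= p.r_max):
        idx = int(np.argmax(np.asarray(r >= p.r_max)))
        raise DivergedBondError(-1, -1, float(np.atleast_1d(r)[idx]))
    x = (r / p.r_max) ** 2
    return (-0.5 * p.K * p.r_max**2 * np.log1p(-x))[()]

def kg_bond_energy(r, pair: PairParams = PairParams(), fene: FeneParams = FeneParams()):
    """Total Kremer-Grest bond energy: FENE attraction plus WCA repulsion."""
    return fene_energy(r, fene) + wca_energy(r, pair)


def angle_energy(phi, p: AngleParams):
    """Harmonic bending energy ``1/2 K (phi - pi)^2`` for a bead triplet.

    ``phi`` is the interior angle; values are clamped to [0, pi].
    """
    phi = np.clip(np.asarray(phi, dtype=float), 0.0, np.pi)
    return (0.5 * p.K_angle * (phi - p.phi0) ** 2)[()]


def harmonic_bond_energy(r, p: HarmonicBondParams = HarmonicBondParams()):
    """Harmonic reaction-bond energy, force-capped at large stretch.

    Quadratic ``1/2 k (r - r0)^2`` within half a bead diameter of the
    rest length, continued linearly beyond (constant restoring force
    ``k/2``), so bonds created far from equilibrium during a catalytic
    event pull their partners together without destabilising the
    integration.
    """
    r = np.asarray(r, dtype=float)
    s = r - p.r0
    quad = 0.5 * p.k * s**2
    lin = 0.5 * p.k * 0.25 + 0.5 * p.k * (np.abs(s) - 0.5)
    return np.where(np.abs(s) <= 0.5, quad, lin)[()]


def kg_bond_rest_length(
    pair: PairParams = PairParams(), fene: FeneParams = FeneParams()
) -> float:
    """Minimum of the combined FENE + WCA bond potential (about 0.97 sigma)."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda r: kg_bond_energy(r, pair, fene),
        bounds=(0.5, min(fene.r_max * 0.999, pair.cutoff)),
        method="bounded",
    )
    return float(res.x)
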