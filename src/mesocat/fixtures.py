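"""Named tiny scenarios for tests and demonstration.

Each fixture is a complete, fast configuration (seconds, one CPU):

- ``single_chain``: one free Kremer-Grest chain in a periodic box.
- ``toy_catalysis``: one catalyst and one short (6-bead) chain, no
  reservoir; the scripted reaction pathway can be replayed by hand.
- ``ideal_gcmc``: point particles exchanged with the reservoir in a
  bulk box (the grand-canonical occupancy statistics are exactly
  Poisson).
- ``mini_slit``: a 2 nm slit pore with two catalysts and a small
  outside volume.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig, parse_config
from .gcmc import ConformerLibrary
from .system import build_linear_chain

SCENARIOS = ("single_chain", "toy_catalysis", "ideal_gcmc", "mini_slit")


def generate_fixture(name: str, seed: int = 0) -> RunConfig:
    """Reproducible tiny scenario configuration."""
    if name == "single_chain":
        return parse_config(
            {
                "seed": seed,
                "geometry": {"kind": "bulk", "L": 15.0},
                "chain": {"n_monomers": 22},
                "catalysts": {"enabled": False},
                "reservoir": {"enabled": False},
                "run": {"n_steps": 20_000, "sample_interval": 500},
            }
        )
    if name == "toy_catalysis":
        return parse_config(
            {
                "seed": seed,
                "geometry": {"kind": "bulk", "L": 8.0, "couple_dist": 2.0},
                "chain": {"n_monomers": 6, "k_angle": 2.0},
                "catalysts": {"enabled": True, "n": 1},
                "reaction": {"tau_break": 5.0},
                "reservoir": {"enabled": False},
                "run": {"n_steps": 50_000, "sample_interval": 1_000},
            }
        )
    if name == "ideal_gcmc":
        return parse_config(
            {
                "seed": seed,
                "geometry": {"kind": "bulk", "L": 10.0},
                "chain": {"n_monomers": 4, "k_angle": 0.0},
                "catalysts": {"enabled": False},
                "reservoir": {"enabled": True, "rho": 0.015,
                              "attempts_per_sweep": 20, "sweep_interval": 100},
                "run": {"n_steps": 100_000, "sample_interval": 100},
            }
        )
    if name == "mini_slit":
        return parse_config(
            {
                "seed": seed,
                "geometry": {
                    "kind": "slit",
                    "d_slit": 2.0,
                    "l": 6.0,
                    "Lout": 10.0,
                    "Ly": 6.0,
                    "Lz": 6.0,
                    "pad": 2.0,
                },
                "chain": {"n_monomers": 22},
                "catalysts": {"enabled": True, "n": 2},
                "reaction": {"tau_break": 10.0},
                "reservoir": {"enabled": True, "rho": 0.015},
                "run": {"n_steps": 100_000, "sample_interval": 1_000},
            }
        )
    raise KeyError(f"unknown fixture '{name}'; choose from {SCENARIOS}")


def point_particle_library() -> ConformerLibrary:
    """Single-bead 'conformer' library for ideal-gas reservoir tests."""
    return ConformerLibrary(
        n_monomers=1,
        k_angle=0.0,
        positions=np.zeros((1, 1, 3)),
        energies=np.zeros(1),
        stride_steps=0,
        seed=0,
    )


def straight_chain_library(n_monomers: int, n_conformers: int = 64,
                           seed: int = 0) -> ConformerLibrary:
    """Cheap stand-in library of slightly jittered straight chains.

    Synthetic: not Boltzmann-sampled; use only where the conformational
    statistics do not matter (plumbing and bookkeeping tests).
    """
    rng = np.random.default_rng(seed)
    confs = np.empty((n_conformers, n_monomers, 3))
    for c in range(n_conformers):
        pos, _ = build_linear_chain(n_monomers, jitter=0.02, rng=rng)
        confs[c] = pos - pos.mean(axis=0)
    return ConformerLibrary(
        n_monomers=n_monomers,
        k_angle=0.0,
        positions=confs,
        energies=np.zeros(n_conformers),
        stride_steps=0,
        seed=seed,
    )
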