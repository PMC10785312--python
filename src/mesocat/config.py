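"""Run configuration: TOML schema, validation, and runner construction.

All lengths are in nm, energies in k_B T, times in the reduced time unit
tau.  Unknown keys are rejected so typos fail loudly.  A configuration
round-trips losslessly through :func:`dumps_toml` / :func:`load_config`.
"""

from __future__ import annotations

import hashlib
import io as _io
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from .geometry import (
    Boundary,
    CatalystLayout,
    COUPLE_DIST_NM,
    CORE_RADIUS_NM,
    L_EX_NM,
    L_PAD_NM,
    SIGMA_CAT_NM2,
    GeometryError,
    catalyst_count,
    place_catalysts,
    place_catalysts_bulk,
)
from .integrate import ModelParams
from .model import (
    FeneParams,
    HarmonicBondParams,
    IntegratorParams,
    PairParams,
    angle_stiffness_for,
)
from .reaction import ReactionParams
from .units import UNITS


class ConfigError(ValueError):
    pass


@dataclass
class GeometryConfig:
    kind: str = "bulk"
    L: float = 10.0  # bulk box edge, nm
    Lx: float = 34.2
    Ly: float = 10.21
    Lz: float = 10.21
    d_slit: float = 2.0
    r: float = 1.15
    l: float = 35.8
    Lout: float = 34.2
    couple_dist: float = COUPLE_DIST_NM
    pad: float = L_PAD_NM


@dataclass
class ChainConfig:
    n_monomers: int = 22
    k_angle: float = -1.0  # <0: use the calibrated value for n_monomers


@dataclass
class CatalystConfig:
    enabled: bool = True
    n: int = -1  # -1: surface-density rule (walled geometries)
    sigma_cat: float = SIGMA_CAT_NM2
    core_radius: float = CORE_RADIUS_NM
    l_ex: float = L_EX_NM
    min_sep: float = 6.0  # bulk catalyst-catalyst separation, nm


@dataclass
class ReactionConfig:
    p_bond: float = 1.0
    tau_break: float = 10.0
    capture_radius: float = 1.0  # sigma
    forward_prob: float = 0.5
    harmonic_k: float = 100.0
    harmonic_r0: float = 0.97


@dataclass
class ReservoirConfig:
    enabled: bool = True
    rho: float = 0.015  # nm^-3
    attempts_per_sweep: int = 10
    sweep_interval: int = 100


@dataclass
class IntegratorConfig:
    dt: float = 0.01
    gamma: float = 1.0


@dataclass
class RunBlockConfig:
    n_steps: int = 100_000
    equilibration_steps: int = 0
    sample_interval: int = 1_000
    trajectory_interval: int = 0  # 0: no trajectory output
    checkpoint_interval: int = 0


@dataclass
class RunConfig:
    seed: int = 0
    replica: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    chain: ChainConfig = field(default_factory=ChainConfig)
    catalysts: CatalystConfig = field(default_factory=CatalystConfig)
    reaction: ReactionConfig = field(default_factory=ReactionConfig)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    run: RunBlockConfig = field(default_factory=RunBlockConfig)

    # -- derived objects ---------------------------------------------------
    @property
    def k_angle(self) -> float:
        if self.chain.k_angle >= 0:
            return self.chain.k_angle
        return angle_stiffness_for(self.chain.n_monomers)

    def boundary(self) -> Boundary:
        g = self.geometry
        if g.kind == "bulk":
            return Boundary.bulk(g.L, couple_dist_nm=g.couple_dist)
        if g.kind == "flat_wall":
            return Boundary.flat_wall(g.Lx, g.Ly, g.Lz,
                                      couple_dist_nm=g.couple_dist)
        if g.kind == "slit":
            return Boundary.slit(g.d_slit, g.l, g.Lout, g.Ly, g.Lz, g.pad)
        if g.kind == "cylinder":
            return Boundary.cylinder(g.r, g.l, g.Lout, g.Ly, g.Lz, g.pad)
        raise ConfigError(f"unknown geometry kind '{g.kind}'")

    def layout(self, boundary: Boundary | None = None) -> CatalystLayout:
        if boundary is None:
            boundary = self.boundary()
        c = self.catalysts
        if not c.enabled:
            return CatalystLayout.empty()
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 0x10CA7, self.replica])
        )
        if boundary.kind == "bulk":
            n = c.n if c.n >= 0 else 1
            return place_catalysts_bulk(n, boundary, rng,
                                        core_radius_nm=c.core_radius,
                                        min_sep_nm=c.min_sep)
        n = None if c.n < 0 else c.n
        return place_catalysts(boundary, rng, n=n, sigma_cat_nm2=c.sigma_cat)

    def model_params(self) -> ModelParams:
        return ModelParams(
            pair=PairParams(),
            fene=FeneParams(),
            harmonic=HarmonicBondParams(
                k=self.reaction.harmonic_k, r0=self.reaction.harmonic_r0
            ),
            k_angle=self.k_angle,
        )

    def integrator_params(self) -> IntegratorParams:
        return IntegratorParams(dt=self.integrator.dt, gamma=self.integrator.gamma)

    def reaction_params(self) -> ReactionParams:
        r = self.reaction
        return ReactionParams(
            p_bond=r.p_bond,
            tau_break=r.tau_break,
            capture_radius=r.capture_radius,
            forward_prob=r.forward_prob,
        )

    def reservoir_spec(self):
        from .gcmc import ReservoirSpec

        if not self.reservoir.enabled:
            return None
        return ReservoirSpec.from_nm3(
            self.reservoir.rho,
            attempts_per_sweep=self.reservoir.attempts_per_sweep,
            sweep_interval=self.reservoir.sweep_interval,
        )

    def hash(self) -> str:
        return hashlib.sha256(dumps_toml(self).encode()).hexdigest()[:16]


_SECTIONS = {
    "geometry": GeometryConfig,
    "chain": ChainConfig,
    "catalysts": CatalystConfig,
    "reaction": ReactionConfig,
    "reservoir": ReservoirConfig,
    "integrator": IntegratorConfig,
    "run": RunBlockConfig,
}


def _coerce(section_cls, data: dict, where: str):
    allowed = {f.name: f.type for f in fields(section_cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{where}]: {sorted(unknown)}")
    obj = section_cls()
    for k, v in data.items():
        cur = getattr(obj, k)
        if isinstance(cur, bool):
            if not isinstance(v, bool):
                raise ConfigError(f"[{where}] {k} must be a boolean")
        elif isinstance(cur, int) and not isinstance(cur, bool):
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                raise ConfigError(f"[{where}] {k} must be a number")
            v = int(v)
        elif isinstance(cur, float):
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                raise ConfigError(f"[{where}] {k} must be a number")
            v = float(v)
        setattr(obj, k, v)
    return obj


def parse_config(data: dict) -> RunConfig:
    unknown = set(data) - set(_SECTIONS) - {"seed", "replica"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = RunConfig()
    cfg.seed = int(data.get("seed", 0))
    cfg.replica = int(data.get("replica", 0))
    for name, cls in _SECTIONS.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ConfigError(f"[{name}] must be a table")
            setattr(cfg, name, _coerce(cls, data[name], name))
    # cross-field validation
    g = cfg.geometry
    if g.kind not in ("bulk", "flat_wall", "slit", "cylinder"):
        raise ConfigError(
            f"geometry.kind must be one of bulk/flat_wall/slit/cylinder, "
            f"got '{g.kind}'"
        )
    if g.kind == "cylinder" and g.r <= 0.7:
        raise GeometryError("cylinder radius must exceed the site offset 0.7 nm")
    if cfg.chain.n_monomers < 4:
        raise ConfigError("chain.n_monomers must be at least 4")
    return cfg


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return parse_config(data)


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return repr(v)


def dumps_toml(cfg: RunConfig) -> str:
    """Serialize a config to TOML (normalized: all keys, fixed order)."""
    out = _io.StringIO()
    out.write(f"seed = {cfg.seed}\n")
    out.write(f"replica = {cfg.replica}\n")
    for name in _SECTIONS:
        out.write(f"\n[{name}]\n")
        for k, v in asdict(getattr(cfg, name)).items():
            out.write(f"{k} = {_fmt_value(v)}\n")
    return out.getvalue()


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(dumps_toml(cfg))
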