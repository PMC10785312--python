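"""High-level entry points: build and execute a configured simulation."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, dumps_toml
from .gcmc import ConformerLibrary, sample_conformer_library
from .integrate import draw_maxwell_velocities
from .io import save_checkpoint, write_timeseries_tsv, write_xyz_frame
from .observables import EndDensityAccumulator
from .runner import Runner
from .system import build_linear_chain
from .units import UNITS


@dataclass
class RunResult:
    """Output bundle of one simulation run."""

    runner: Runner
    config: RunConfig
    outdir: Path | None = None

    @property
    def ledger(self):
        return self.runner.ledger

    @property
    def series(self):
        return self.runner.series


def build_runner(config: RunConfig, library: ConformerLibrary | None = None,
                 populate: bool = True) -> Runner:
    """Construct a ready-to-run :class:`Runner` from a configuration.

    If the reservoir is enabled and no conformer library is given, a
    moderately sized one is sampled on the fly.  Runs without a reservoir
    start from a single substrate chain at the box centre.  With
    ``populate=False`` the system starts empty and fills from the
    reservoir (useful when the initial uniform filling would overstuff a
    slowly draining pore).
    """
    boundary = config.boundary()
    layout = config.layout(boundary)
    spec = config.reservoir_spec()
    if spec is not None and library is None:
        n_m = config.chain.n_monomers
        if n_m == 1:
            from .fixtures import point_particle_library

            library = point_particle_library()
        else:
            library = sample_conformer_library(
                n_m, config.k_angle, n_samples=2_000,
                seed=int(np.random.SeedSequence([config.seed, 0x11B]).generate_state(1)[0] % (2**31)),
            )
    runner = Runner(
        boundary=boundary,
        layout=layout,
        mp=config.model_params(),
        ip=config.integrator_params(),
        seed=config.seed + 1_000_003 * config.replica,
        rp=config.reaction_params(),
        reservoir_spec=spec,
        library=library,
        reactions_on=config.catalysts.enabled,
        populate=populate,
    )
    if spec is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
        n_m = config.chain.n_monomers
        pos, labeled = build_linear_chain(
            n_m,
            origin=tuple(boundary.box / 2 - np.array([0.97 * n_m / 2, 0, 0])),
            jitter=0.02,
            rng=rng,
        )
        runner.system.add_molecule(
            pos, draw_maxwell_velocities(n_m, runner.ip.temperature, rng), labeled
        )
    return runner


def run_simulation(
    config: RunConfig,
    library: ConformerLibrary | None = None,
    outdir=None,
    observers: list | None = None,
) -> RunResult:
    """Run a configured simulation end to end.

    Writes, when ``outdir`` is given: a manifest (config, hash, seed), the
    reaction event ledger and scalar time series as TSV, the realized
    catalyst layout, an extended-XYZ trajectory (if enabled) and a final
    checkpoint.
    """
    runner = build_runner(config, library)
    out = Path(outdir) if outdir is not None else None
    traj_fh = None
    obs = list(observers or [])
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "config": dumps_toml(config),
                    "config_hash": config.hash(),
                    "seed": config.seed,
                    "replica": config.replica,
                    "version": _version(),
                },
                indent=2,
            )
        )
        layout = runner.layout
        pd.DataFrame(
            {
                "catalyst": np.repeat(np.arange(layout.n_catalysts), 2),
                "site": np.arange(len(layout.site_pos)),
                "x_nm": UNITS.to_nm(layout.site_pos[:, 0]),
                "y_nm": UNITS.to_nm(layout.site_pos[:, 1]),
                "z_nm": UNITS.to_nm(layout.site_pos[:, 2]),
            }
        ).to_csv(out / "layout.tsv", sep="\t", index=False)
        if config.run.trajectory_interval > 0:
            traj_fh = open(out / "trajectory.xyz", "w")
            stride = max(
                1, config.run.trajectory_interval // max(1, config.run.sample_interval)
            )
            counter = {"i": 0}

            def _write_frame(system, boundary):
                if counter["i"] % stride == 0:
                    write_xyz_frame(traj_fh, system, boundary)
                counter["i"] += 1

            obs.append(_write_frame)
    if config.run.equilibration_steps > 0:
        runner.run(config.run.equilibration_steps)
    runner.run(
        config.run.n_steps,
        sample_interval=config.run.sample_interval,
        observers=obs,
    )
    if traj_fh is not None:
        traj_fh.close()
    if out is not None:
        runner.ledger.write_tsv(out / "ledger.tsv")
        write_timeseries_tsv(out / "timeseries.tsv", runner.series.to_arrays())
        save_checkpoint(runner, out / "checkpoint.npz")
    return RunResult(runner=runner, config=config, outdir=out)


def _version() -> str:
    from . import __version__

    return __version__
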