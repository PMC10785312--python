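"""Trajectory, ledger and checkpoint I/O.

Trajectories are extended XYZ (one block per frame, a ``Properties=``
comment line, per-bead columns: species, molecule id, lineage tag, label
flag).  Scalar logs and event ledgers are TSV with a header line.
Checkpoints are npz containers plus an embedded JSON blob for the
non-array state (molecule registry, catalyst states, RNG streams), enough
to restore a run bit-identically.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .geometry import Boundary
from .system import System
from .units import UNITS


def write_xyz_frame(fh, system: System, boundary: Boundary, comment: str = "") -> None:
    """Append one extended-XYZ frame (coordinates in nm)."""
    box_nm = UNITS.to_nm(boundary.box)
    n = system.n_beads
    fh.write(f"{n}\n")
    lattice = f'Lattice="{box_nm[0]} 0 0 0 {box_nm[1]} 0 0 0 {box_nm[2]}"'
    props = "Properties=species:S:1:pos:R:3:mol:I:1:lineage:I:1:label:I:1"
    fh.write(f"{lattice} {props} time_tau={system.time} {comment}\n".strip() + "\n")
    pos_nm = UNITS.to_nm(system.pos)
    for i in range(n):
        sp = "C" if system.lineage[i] >= 0 else "X"
        fh.write(
            f"{sp} {pos_nm[i, 0]:.6f} {pos_nm[i, 1]:.6f} {pos_nm[i, 2]:.6f} "
            f"{int(system.mol_id[i])} {int(system.lineage[i])} "
            f"{int(system.labeled[i])}\n"
        )


def read_xyz_frames(path) -> list[pd.DataFrame]:
    """Read the per-bead tables of every frame of an extended-XYZ file."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            rows = []
            for _ in range(n):
                sp, x, y, z, mol, lin, lab = fh.readline().split()
                rows.append(
                    (sp, float(x), float(y), float(z), int(mol), int(lin), int(lab))
                )
            frames.append(
                pd.DataFrame(
                    rows,
                    columns=["species", "x", "y", "z", "mol", "lineage", "label"],
                )
            )
    return frames


def write_timeseries_tsv(path, series_dict: dict) -> None:
    pd.DataFrame(series_dict).to_csv(path, sep="\t", index=False)


def save_checkpoint(runner, path) -> None:
    """Serialize the full mutable state of a :class:`~mesocat.runner.Runner`."""
    sys_ = runner.system
    bonds = np.array(
        [[i, j, k] for (i, j, k) in sys_.bonds], dtype=np.int64
    ).reshape(-1, 3)
    meta = {
        "mol_kind": {str(k): v for k, v in sys_.mol_kind.items()},
        "tethers": {str(k): int(v) for k, v in sys_.tethers.items()},
        "time": sys_.time,
        "next_mol_id": sys_.next_mol_id,
        "next_lineage": sys_.next_lineage,
        "step": runner.step,
        "global_step": runner.driver.global_step,
        "rng_react": runner.rng_react.bit_generator.state,
        "rng_gcmc": runner.rng_gcmc.bit_generator.state,
        "catalysts": [
            {
                "index": c.index,
                "sites": list(c.sites),
                "bound_site": c.bound_site,
                "bound_bead": c.bound_bead,
                "ring_c0": c.ring_c0,
                "ring_c1": c.ring_c1,
                "ring_c2": c.ring_c2,
                "ring_site_c1": c.ring_site_c1,
                "breakup_time": (
                    c.breakup_time if np.isfinite(c.breakup_time) else None
                ),
            }
            for c in runner.catalysts
        ],
        "ledger": {
            "events": runner.ledger.events,
            "n_rc": runner.ledger.n_rc,
            "n_p": runner.ledger.n_p,
            "n_byproduct": runner.ledger.n_byproduct,
            "n_transfer": runner.ledger.n_transfer,
        },
        "gcmc_stats": (
            vars(runner.reservoir.stats) if runner.reservoir is not None else None
        ),
    }
    np.savez_compressed(
        path,
        pos=sys_.pos,
        vel=sys_.vel,
        mol_id=sys_.mol_id,
        lineage=sys_.lineage,
        labeled=sys_.labeled,
        in_capture=sys_.in_capture,
        bonds=bonds,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_checkpoint(runner, path) -> None:
    """Restore a runner previously saved with :func:`save_checkpoint`.

    The runner must have been constructed with the same configuration
    (boundary, layout, parameters, seed); continuation is then
    bit-identical to the unsplit run.
    """
    d = np.load(path)
    meta = json.loads(bytes(d["meta"]).decode())
    sys_ = runner.system
    sys_.pos = d["pos"].copy()
    sys_.vel = d["vel"].copy()
    sys_.mol_id = d["mol_id"].copy()
    sys_.lineage = d["lineage"].copy()
    sys_.labeled = d["labeled"].copy()
    sys_.in_capture = d["in_capture"].copy()
    sys_.bonds = [(int(i), int(j), int(k)) for i, j, k in d["bonds"]]
    sys_.mol_kind = {int(k): v for k, v in meta["mol_kind"].items()}
    sys_.tethers = {int(k): int(v) for k, v in meta["tethers"].items()}
    sys_.time = float(meta["time"])
    sys_.next_mol_id = int(meta["next_mol_id"])
    sys_.next_lineage = int(meta["next_lineage"])
    sys_.invalidate()
    runner.step = int(meta["step"])
    runner.driver.global_step = int(meta["global_step"])
    runner.rng_react.bit_generator.state = meta["rng_react"]
    runner.rng_gcmc.bit_generator.state = meta["rng_gcmc"]
    from .reaction import Catalyst

    runner.catalysts = [
        Catalyst(
            index=c["index"],
            sites=tuple(c["sites"]),
            bound_site=c["bound_site"],
            bound_bead=c["bound_bead"],
            ring_c0=c["ring_c0"],
            ring_c1=c["ring_c1"],
            ring_c2=c["ring_c2"],
            ring_site_c1=c["ring_site_c1"],
            breakup_time=(
                c["breakup_time"] if c["breakup_time"] is not None else np.inf
            ),
        )
        for c in meta["catalysts"]
    ]
    led = runner.ledger
    led.events = [tuple(e) for e in meta["ledger"]["events"]]
    led.n_rc = meta["ledger"]["n_rc"]
    led.n_p = meta["ledger"]["n_p"]
    led.n_byproduct = meta["ledger"]["n_byproduct"]
    led.n_transfer = meta["ledger"]["n_transfer"]
    if runner.reservoir is not None and meta["gcmc_stats"] is not None:
        for k, v in meta["gcmc_stats"].items():
            setattr(runner.reservoir.stats, k, v)
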