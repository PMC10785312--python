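"""Metathesis event engine: hand replay of the catalytic cycle on a toy
chain, bookkeeping invariants, breakup-time statistics, classification.

networkx is used as the independent graph oracle (cycle detection,
connected components) against the engine's own bookkeeping.
"""

import networkx as nx
import numpy as np
import pytest

from mesocat.geometry import Boundary, place_catalysts_bulk
from mesocat.integrate import ModelParams
from mesocat.reaction import (
    ReactionLedger,
    ReactionParams,
    apply_breakup,
    attempt_binding,
    classify_release,
    draw_breakup_time,
    initialize_catalysts,
    site_accept_array,
)
from mesocat.system import (
    BOND_FENE,
    BOND_HARMONIC,
    CAP_LINEAGE,
    System,
    build_linear_chain,
)


def _graph(system):
    g = nx.Graph()
    g.add_nodes_from(range(system.n_beads))
    g.add_edges_from((i, j) for i, j, _ in system.bonds)
    return g


def _place_for_binding(s, c1, target, direction):
    """Rigidly move c1's molecule so c1 sits at ``target`` with its
    chain running along ``direction`` (so C2 ends up near the carbene)."""
    beads = sorted(s.connected_component(int(c1)))
    idx = np.array(beads)
    # orient the molecule's local chain axis along `direction`
    other = beads[1] if beads[0] == c1 else beads[0]
    cur = s.pos[int(other)] - s.pos[int(c1)]
    cur /= np.linalg.norm(cur)
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)
    v = np.cross(cur, d)
    c = float(np.dot(cur, d))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    rel = s.pos[idx] - s.pos[int(c1)]
    s.pos[idx] = rel @ rot.T + np.asarray(target, float)
    s.invalidate()


def _bind_here(s, cats, cat, layout, c1, rp, rng, t, led):
    """Place c1 in the free-site capture volume with its labeled partner
    toward the carbene C0, then fire the binding trial (a collision
    implies exactly this proximity)."""
    site = layout.site_pos[cat.free_site]
    c0 = cat.bound_bead
    toward_c0 = s.pos[c0] - site
    n = np.linalg.norm(toward_c0)
    toward_c0 = toward_c0 / n if n > 1e-9 else np.array([1.0, 0, 0])
    s.pos[int(c1)] = site + 0.1 * toward_c0
    partner = s.pair_partner(int(c1))
    if partner is not None:
        s.pos[int(partner)] = site + min(0.97, max(0.3, n - 0.97)) * toward_c0
    s.invalidate()
    from mesocat.reaction import attempt_binding as _ab

    return _ab(s, cats, cat.free_site, int(c1), rp, rng, t, led)


def _toy(rng, n_beads=6):
    """One catalyst (cap on site 0) plus one short labeled chain."""
    b = Boundary.bulk(8.0, couple_dist_nm=2.0)
    layout = place_catalysts_bulk(1, b, rng)
    s = System.empty()
    cats = initialize_catalysts(s, layout, rng)
    pos, lab = build_linear_chain(n_beads, origin=(5.0, 5.0, 5.0))
    s.add_molecule(pos, np.zeros((n_beads, 3)), lab)
    return s, b, layout, cats


@pytest.fixture()
def toy(rng):
    return _toy(rng)


class TestRestingState:
    def test_cap_initialization(self, toy):
        s, b, layout, cats = toy
        cat = cats[0]
        assert cat.bound_bead >= 0 and not cat.has_ring
        assert len(s.tethers) == 1
        assert s.lineage[cat.bound_bead] == CAP_LINEAGE
        assert s.labeled[cat.bound_bead]
        assert cat.free_site != cat.bound_site
        acc = site_accept_array(cats, 2)
        assert acc[cat.free_site] == 1 and acc[cat.bound_site] == 0


class TestCatalyticCycle:
    """Full hand replay: initiation releases the 2-bead ethylene analog,
    ring closure releases a cycle, every intermediate graph is checked."""

    def test_initiation_inner_bead_first(self, toy, rng):
        s, b, layout, cats = toy
        cat = cats[0]
        cap = cat.bound_bead
        chain = s.beads_of(1)
        inner = int(chain[1])  # second bead of the labeled end pair
        rp = ReactionParams(tau_break=5.0)
        led = ReactionLedger()
        bonds_before = len(s.bonds)
        ok = _bind_here(s, cats, cat, layout, inner, rp, rng, 0.0, led)
        assert ok and cat.has_ring
        # 4-ring: two tethers + the new harmonic C0-C2 bond + chain bond C1-C2
        assert len(s.tethers) == 2
        assert (cap, int(chain[0]), BOND_HARMONIC) in [
            (min(i, j), max(i, j), k) if cap < chain[0] else (i, j, k)
            for i, j, k in s.bonds
        ] or any(
            {i, j} == {cap, int(chain[0])} and k == BOND_HARMONIC
            for i, j, k in s.bonds
        )
        assert len(s.bonds) == bonds_before + 1
        # no further binding while mid-cycle
        assert cat.free_site == -1
        assert site_accept_array(cats, 2).sum() == 0
        # forward breakup frees the cap + outer bead as the 2-bead byproduct
        rel = apply_breakup(s, cats, cat, "forward", 1.0, led)
        assert len(rel) == 1
        mol, cls = rel[0]
        assert cls == "byproduct"
        assert len(s.beads_of(mol)) == 2
        assert led.n_byproduct == 1 and led.n_rc == 0 and led.n_p == 0
        # chain (minus its outer bead) is attached via the former inner bead
        assert cat.bound_bead == inner
        comp = nx.node_connected_component(_graph(s), inner)
        assert len(comp) == 5

    def test_ring_closure_outer_bead_first(self, toy, rng):
        s, b, layout, cats = toy
        cat = cats[0]
        rp = ReactionParams(tau_break=5.0)
        led = ReactionLedger()
        chain = s.beads_of(1)
        # initiation with the inner bead, forward
        assert _bind_here(s, cats, cat, layout, int(chain[1]), rp, rng, 0.0, led)
        apply_breakup(s, cats, cat, "forward", 1.0, led)
        # now the far end arrives, outermost bead first
        outer = int(chain[-1])
        ok = _bind_here(s, cats, cat, layout, outer, rp, rng, 2.0, led)
        assert ok
        rel = apply_breakup(s, cats, cat, "forward", 3.0, led)
        assert [cls for _, cls in rel] == ["rc"]
        mol, _ = rel[0]
        ring = s.beads_of(mol)
        assert len(ring) == 4  # 6-mer minus initiation loss minus new carbene
        # independent cycle oracle
        sub = _graph(s).subgraph(ring.tolist())
        assert len(nx.cycle_basis(sub.copy())) == 1
        assert led.n_rc == 1
        # the new carbene is a lone bead retagged as cap
        assert s.lineage[cat.bound_bead] == CAP_LINEAGE
        assert len(nx.node_connected_component(_graph(s), cat.bound_bead)) == 1

    def test_backward_breakup_is_exact_inverse(self, toy, rng):
        s, b, layout, cats = toy
        cat = cats[0]
        rp = ReactionParams(tau_break=5.0)
        led = ReactionLedger()
        chain = s.beads_of(1)
        bonds_before = sorted(
            (min(i, j), max(i, j), k) for i, j, k in s.bonds
        )
        tethers_before = dict(s.tethers)
        assert _bind_here(s, cats, cat, layout, int(chain[1]), rp, rng, 0.0, led)
        apply_breakup(s, cats, cat, "backward", 1.0, led)
        assert sorted(
            (min(i, j), max(i, j), k) for i, j, k in s.bonds
        ) == bonds_before
        assert dict(s.tethers) == tethers_before
        assert not cat.has_ring and cat.bound_bead == tethers_before[
            cat.bound_site
        ]
        assert led.n_productive == 0

    def test_polymerization_two_lineages(self, rng):
        """A second substrate joining an attached chain releases an open
        chain carrying both backbones -> P."""
        s, b, layout, cats = _toy(rng)
        cat = cats[0]
        rp = ReactionParams(tau_break=5.0)
        led = ReactionLedger()
        chain_x = s.beads_of(1)
        assert _bind_here(s, cats, cat, layout, int(chain_x[1]), rp, rng, 0.0, led)
        apply_breakup(s, cats, cat, "forward", 1.0, led)  # byproduct out
        # add a second substrate; its outer bead binds first
        pos, lab = build_linear_chain(6, origin=(5.0, 6.5, 5.0))
        mol_y = s.add_molecule(pos, np.zeros((6, 3)), lab)
        chain_y = s.beads_of(mol_y)
        assert _bind_here(s, cats, cat, layout, int(chain_y[0]), rp, rng, 2.0, led)
        rel = apply_breakup(s, cats, cat, "forward", 3.0, led)
        assert [cls for _, cls in rel] == ["p"]
        mol, _ = rel[0]
        joined = s.beads_of(mol)
        assert len(joined) == 10  # 5 (X minus outer bead) + 5 (Y minus carbene)
        lineages = {int(l) for l in s.lineage[joined] if l != CAP_LINEAGE}
        assert len(lineages) == 2
        sub = _graph(s).subgraph(joined.tolist())
        assert nx.is_tree(sub)  # open chain, no cycle
        assert led.n_p == 1

    def test_end_group_exchange_is_transfer_not_p(self, rng):
        """When the inner bead of the visiting pair binds first, the
        released molecule is one backbone plus a single foreign carbon:
        chain transfer, not a polymerization."""
        s, b, layout, cats = _toy(rng)
        cat = cats[0]
        rp = ReactionParams(tau_break=5.0)
        led = ReactionLedger()
        chain_x = s.beads_of(1)
        assert _bind_here(s, cats, cat, layout, int(chain_x[1]), rp, rng, 0.0, led)
        apply_breakup(s, cats, cat, "forward", 1.0, led)
        pos, lab = build_linear_chain(6, origin=(5.0, 6.5, 5.0))
        mol_y = s.add_molecule(pos, np.zeros((6, 3)), lab)
        chain_y = s.beads_of(mol_y)
        assert _bind_here(s, cats, cat, layout, int(chain_y[1]), rp, rng, 2.0, led)
        rel = apply_breakup(s, cats, cat, "forward", 3.0, led)
        assert [cls for _, cls in rel] == ["transfer"]
        assert led.n_p == 0 and led.n_transfer == 1
        # the catalyst kept the rest of chain Y
        comp = nx.node_connected_component(_graph(s), cat.bound_bead)
        assert len(comp) == 5


class TestBreakupTimes:
    def test_exponential_mean(self, rng):
        rp = ReactionParams(tau_break=7.0)
        draws = np.array([draw_breakup_time(rp, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(7.0, rel=0.015)

    def test_memorylessness(self, rng):
        rp = ReactionParams(tau_break=7.0)
        draws = np.array([draw_breakup_time(rp, rng) for _ in range(200_000)])
        cond = draws[draws > 7.0] - 7.0
        assert cond.mean() == pytest.approx(7.0, rel=0.03)


class TestClassification:
    def test_classify_requires_detached_component(self, toy):
        s, b, layout, cats = toy
        cap = cats[0].bound_bead
        with pytest.raises(ValueError):
            classify_release(s, {int(cap)})

    def test_unlabeled_bead_never_binds(self, toy, rng):
        s, b, layout, cats = toy
        mid = int(s.beads_of(1)[3])  # backbone bead, unlabeled
        assert not s.labeled[mid]
        led = ReactionLedger()
        ok = attempt_binding(
            s, cats, cats[0].free_site, mid, ReactionParams(), rng, 0.0, led
        )
        assert not ok

    def test_ledger_roundtrip(self, tmp_path, toy, rng):
        s, b, layout, cats = toy
        rp = ReactionParams(tau_break=5.0)
        led = ReactionLedger()
        chain = s.beads_of(1)
        assert _bind_here(s, cats, cats[0], layout, int(chain[1]), rp, rng,
                          0.0, led)
        apply_breakup(s, cats, cats[0], "forward", 1.0, led)
        path = tmp_path / "ledger.tsv"
        led.write_tsv(path)
        led2 = ReactionLedger.read_tsv(path)
        assert led2.n_byproduct == led.n_byproduct == 1
        assert len(led2.events) == len(led.events)


class TestCompactionRemap:
    def test_catalyst_indices_survive_molecule_removal(self, rng):
        """Deleting molecules compacts bead storage; the catalyst's bound
        bead (and ring members) must be remapped together with the tether
        map."""
        from mesocat.api import build_runner
        from mesocat.config import parse_config
        from mesocat.fixtures import straight_chain_library

        cfg = parse_config(
            {
                "seed": 2,
                "geometry": {"kind": "bulk", "L": 10.0, "couple_dist": 2.0},
                "chain": {"n_monomers": 6, "k_angle": 1.0},
                "catalysts": {"enabled": True, "n": 1},
                "reservoir": {"enabled": True, "rho": 0.02},
            }
        )
        r = build_runner(cfg, straight_chain_library(6))
        s = r.system
        cat = r.catalysts[0]
        assert s.tethers[cat.bound_site] == cat.bound_bead
        # remove a few untethered substrates through the reservoir path
        from mesocat.system import MOL_SUBSTRATE

        victims = [
            m for m in s.molecules(MOL_SUBSTRATE)
        ][:3]
        assert victims, "fixture needs populated substrates"
        new_index = s.remove_molecules(victims)
        r._remap_catalyst_beads(new_index)
        assert s.tethers[cat.bound_site] == cat.bound_bead
        assert s.lineage[cat.bound_bead] == CAP_LINEAGE

    def test_sweep_keeps_tether_and_catalyst_consistent(self, rng):
        from mesocat.api import build_runner
        from mesocat.config import parse_config
        from mesocat.fixtures import straight_chain_library

        cfg = parse_config(
            {
                "seed": 7,
                "geometry": {"kind": "bulk", "L": 8.0, "couple_dist": 2.0},
                "chain": {"n_monomers": 6, "k_angle": 1.0},
                "catalysts": {"enabled": True, "n": 1},
                "reservoir": {"enabled": True, "rho": 0.05,
                              "attempts_per_sweep": 30},
            }
        )
        r = build_runner(cfg, straight_chain_library(6))
        for _ in range(30):
            r.reservoir.sweep(r.system)
            cat = r.catalysts[0]
            assert r.system.tethers[cat.bound_site] == cat.bound_bead
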