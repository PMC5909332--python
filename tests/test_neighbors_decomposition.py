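"""Linked cells vs the O(N²) oracle, midpoint pair ownership, halo coverage
and load rebalancing."""

import numpy as np
import pytest
from _helpers import brute_force_pairs

from polarmd.decomposition import (BlockGrid, halo_atoms, midpoint_owner,
                                   midpoint_owners, partition_pairs,
                                   rebalance_blocks)
from polarmd.neighbors import CellGrid, NeighborList
from polarmd.system import ConfigurationError, SimulationBox


class TestCellGrid:
    def test_single_atom_single_cell(self):
        box = SimulationBox.cubic(10.0)
        g = CellGrid(np.array([[1.0, 2.0, 3.0]]), box, 4.0)
        assert len(g.occupied()) == 1

    def test_cube_corners_in_octants(self):
        box = SimulationBox.cubic(10.0)
        pts = np.array([[x, y, z] for x in (2.5, 7.5) for y in (2.5, 7.5)
                        for z in (2.5, 7.5)])
        g = CellGrid(pts, box, 5.0)
        assert len(g.occupied()) == 8
        assert all(len(v) == 1 for v in g.occupied().values())

    def test_cutoff_too_large(self):
        box = SimulationBox.cubic(10.0)
        with pytest.raises(ConfigurationError):
            CellGrid(np.zeros((1, 3)), box, 6.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cell_pairs_match_n2_oracle(self, seed):
        rng = np.random.default_rng(seed)
        box = SimulationBox.cubic(20.0)
        pos = rng.uniform(0, 20, size=(500, 3))
        nl = NeighborList(pos, box, 5.0, skin=0.0)
        got = set(zip(*map(tuple, nl._pairs_cells(pos, 5.0))))
        assert got == brute_force_pairs(pos, box, 5.0)


class TestNeighborList:
    def test_beyond_cutoff_plus_skin_empty(self):
        box = SimulationBox.cubic(20.0)
        pos = np.array([[0.0, 0, 0], [6.1, 0, 0]])
        nl = NeighborList(pos, box, 5.0, skin=1.0)
        assert len(nl.pairs[0]) == 0

    def test_periodic_wrap_pair_listed(self):
        box = SimulationBox.cubic(20.0)
        pos = np.array([[0.5, 0, 0], [19.5, 0, 0]])   # wrapped distance 1 Å
        nl = NeighborList(pos, box, 5.0, skin=1.0)
        assert len(nl.pairs[0]) == 1

    def test_random_1000_matches_oracle(self):
        rng = np.random.default_rng(7)
        box = SimulationBox.cubic(25.0)
        pos = rng.uniform(0, 25, size=(1000, 3))
        nl = NeighborList(pos, box, 6.0, skin=0.0)
        got = set(zip(nl.pairs[0].tolist(), nl.pairs[1].tolist()))
        assert got == brute_force_pairs(pos, box, 6.0)

    def test_rebuild_policy(self):
        rng = np.random.default_rng(1)
        box = SimulationBox.cubic(20.0)
        pos = rng.uniform(0, 20, size=(50, 3))
        nl = NeighborList(pos, box, 5.0, skin=1.0)
        assert not nl.needs_rebuild(pos + 0.2)      # below skin/2
        assert nl.needs_rebuild(pos + 0.6)


class TestMidpoint:
    def setup_method(self):
        self.box = SimulationBox.cubic(12.0)
        self.grid = BlockGrid(self.box, (3, 3, 3))

    def test_boundary_atom_owned_by_higher_block(self):
        # atom exactly on the x = 4.0 plane belongs to the second block
        idx = self.grid.block_of_coords(np.array([[4.0, 1.0, 1.0]]))
        assert idx[0, 0] == 1

    def test_lattice_one_atom_per_block(self):
        centers = np.array([[2.0 + 4 * i, 2.0 + 4 * j, 2.0 + 4 * k]
                            for i in range(3) for j in range(3)
                            for k in range(3)])
        counts = self.grid.counts_per_block(centers)
        assert np.all(counts == 1)

    def test_same_block_pair(self):
        xi = np.array([1.0, 1.0, 1.0])
        xj = np.array([2.0, 2.0, 2.0])
        b = midpoint_owner(self.grid, xi, xj)
        assert b == self.grid.assign(np.array([xi]))[0]

    def test_adjacent_blocks_midpoint_decides(self):
        xi = np.array([3.0, 1.0, 1.0])
        xj = np.array([4.4, 1.0, 1.0])      # midpoint 3.7 -> first block
        assert midpoint_owner(self.grid, xi, xj) == \
            self.grid.assign(np.array([[3.7, 1.0, 1.0]]))[0]

    @pytest.mark.parametrize("nb", [1, 2, 3, 4])
    def test_partition_covers_each_pair_once(self, nb):
        rng = np.random.default_rng(nb)
        pos = rng.uniform(0, 12, size=(300, 3))
        grid = BlockGrid(self.box, (nb, nb, nb))
        oracle = brute_force_pairs(pos, self.box, 4.0)
        pi = np.array([p[0] for p in sorted(oracle)])
        pj = np.array([p[1] for p in sorted(oracle)])
        parts = partition_pairs(grid, pos, (pi, pj))
        seen = []
        for b, (bi, bj) in parts.items():
            seen += list(zip(bi.tolist(), bj.tolist()))
        assert len(seen) == len(oracle)
        assert set(seen) == oracle

    def test_reassign_changes_only_boundary_crossers(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 12, size=(200, 3))
        before = self.grid.assign(pos)
        moved = pos + rng.normal(scale=0.05, size=pos.shape)
        after = self.grid.assign(moved)
        recomputed = self.grid.flat(self.grid.block_of_coords(moved))
        assert np.array_equal(after, recomputed)


class TestHalo:
    def test_zero_halo_returns_nothing_extra(self):
        box = SimulationBox.cubic(12.0)
        grid = BlockGrid(box, (2, 2, 2))
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 12, size=(50, 3))
        assert len(halo_atoms(grid, 0, pos, 0.0)) == 0

    def test_face_atom_within_halo(self):
        box = SimulationBox.cubic(12.0)
        grid = BlockGrid(box, (2, 2, 2))
        # block 0 spans [0,6)³; an atom just outside the x face
        pos = np.array([[6.0 + 1.99, 1.0, 1.0]])
        assert 0 in halo_atoms(grid, 0, pos, 2.0)
        assert len(halo_atoms(grid, 0, pos, 1.5)) == 0

    def test_halo_too_large(self):
        box = SimulationBox.cubic(12.0)
        grid = BlockGrid(box, (2, 2, 2))
        with pytest.raises(ConfigurationError):
            halo_atoms(grid, 0, np.zeros((1, 3)), 7.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_midpoint_pairs_computable_from_owned_plus_halo(self, seed):
        rc = 4.0
        box = SimulationBox.cubic(12.0)
        grid = BlockGrid(box, (3, 3, 3))
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 12, size=(150, 3))
        oracle = sorted(brute_force_pairs(pos, box, rc))
        pi = np.array([p[0] for p in oracle])
        pj = np.array([p[1] for p in oracle])
        owners = midpoint_owners(grid, pos, (pi, pj))
        all_owner = grid.assign(pos)
        for b in range(grid.n_blocks):
            avail = set(np.nonzero(all_owner == b)[0]) | \
                set(halo_atoms(grid, b, pos, rc / 2.0))
            for k in np.nonzero(owners == b)[0]:
                assert pi[k] in avail and pj[k] in avail


class TestRebalance:
    def test_uniform_gas_nearly_unchanged(self):
        box = SimulationBox.cubic(12.0)
        grid = BlockGrid(box, (2, 2, 2))
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 12, size=(4000, 3))
        new = rebalance_blocks(grid, pos)
        for ax in range(3):
            assert np.allclose(new.bounds[ax], grid.bounds[ax], atol=0.6)

    def test_clustered_gas_improves(self):
        box = SimulationBox.cubic(12.0)
        grid = BlockGrid(box, (2, 2, 2))
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 5.5, size=(500, 3))    # all in one octant
        c0 = grid.counts_per_block(pos)
        r0 = c0.max() / max(c0.min(), 1)
        new = rebalance_blocks(grid, pos)
        c1 = new.counts_per_block(pos)
        r1 = c1.max() / max(c1.min(), 1)
        assert r1 < r0

    def test_idempotent_once_balanced(self):
        box = SimulationBox.cubic(12.0)
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 12, size=(2000, 3))
        g1 = rebalance_blocks(BlockGrid(box, (2, 2, 2)), pos)
        g2 = rebalance_blocks(g1, pos)
        c1 = g1.counts_per_block(pos)
        c2 = g2.counts_per_block(pos)
        assert c2.max() / max(c2.min(), 1) <= c1.max() / max(c1.min(), 1)


def test_blockwise_energy_equals_global():
    """Summing pair energies over midpoint-owned per-block lists reproduces
    the global pair loop to near machine precision."""
    from polarmd.electrostatics import real_space_permanent
    from polarmd.fixtures import gen_random_multipole_gas

    system, params = gen_random_multipole_gas(60, edge=12.0, seed=9,
                                              polarizable=False)
    box = system.box
    pos = system.positions
    oracle = sorted(brute_force_pairs(pos, box, 5.0))
    pi = np.array([p[0] for p in oracle])
    pj = np.array([p[1] for p in oracle])
    q = np.array([params.multipoles[t].charge for t in system.atom_types])
    mu = np.array([params.multipoles[t].dipole for t in system.atom_types])
    Q = np.array([params.multipoles[t].quadrupole
                  for t in system.atom_types])
    ones = np.ones(len(pi))
    full = real_space_permanent(pos, box, (pi, pj), q, mu, Q, 0.5, ones)
    grid = BlockGrid(box, (3, 3, 3))
    parts = partition_pairs(grid, pos, (pi, pj))
    e_sum = 0.0
    f_sum = np.zeros_like(full["forces"])
    for b, (bi, bj) in parts.items():
        r = real_space_permanent(pos, box, (bi, bj), q, mu, Q, 0.5,
                                 np.ones(len(bi)))
        e_sum += r["energy"]
        f_sum += r["forces"]
    assert abs(e_sum - full["energy"]) <= 1e-12 * abs(full["energy"])
    assert np.allclose(f_sum, full["forces"], atol=1e-10)
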