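"""Serial emulation of the 3D block (domain) decomposition with midpoint
pair ownership.

Blocks tile the periodic box with per-axis half-open intervals [lo, hi); an
atom belongs to the block whose intervals contain its wrapped coordinate
(boundary atoms go to the higher-index block).  A pair is owned by the block
containing the midpoint of its minimum-image segment, so each block needs to
import ("halo") atoms within r_c/2 of its faces.  Load balancing moves the
interval planes toward per-axis coordinate quantiles.
"""

from __future__ import annotations

import numpy as np

from .system import ConfigurationError


class BlockGrid:
    """Spatial blocks with explicit per-axis boundary planes."""

    def __init__(self, box, counts, bounds=None):
        if not box.periodic:
            raise ConfigurationError("block decomposition requires a periodic box")
        self.box = box
        self.counts = tuple(int(c) for c in counts)
        if any(c < 1 for c in self.counts):
            raise ConfigurationError("block counts must be >= 1")
        L = box.lengths
        if bounds is None:
            bounds = [np.linspace(0.0, L[ax], self.counts[ax] + 1)
                      for ax in range(3)]
        self.bounds = [np.asarray(b, dtype=float) for b in bounds]

    @property
    def n_blocks(self):
        return self.counts[0] * self.counts[1] * self.counts[2]

    def block_of_coords(self, pos):
        """Block triple indices for wrapped positions (half-open intervals)."""
        pos = self.box.wrap(pos)
        idx = np.empty((pos.shape[0], 3), dtype=np.int64)
        for ax in range(3):
            # right bound belongs to the next block: searchsorted side='right'
            k = np.searchsorted(self.bounds[ax], pos[:, ax], side="right") - 1
            idx[:, ax] = np.clip(k, 0, self.counts[ax] - 1)
            # points exactly at the top edge wrap to block 0
            idx[pos[:, ax] >= self.bounds[ax][-1], ax] = 0
        return idx

    def flat(self, idx):
        return (idx[:, 0] * self.counts[1] + idx[:, 1]) * self.counts[2] + idx[:, 2]

    def assign(self, positions):
        """Owner block (flat id) per atom — the 'reassign' step."""
        return self.flat(self.block_of_coords(positions))

    def block_bounds(self, flat_id):
        b1, rem = divmod(flat_id, self.counts[1] * self.counts[2])
        b2, b3 = divmod(rem, self.counts[2])
        return [(self.bounds[0][b1], self.bounds[0][b1 + 1]),
                (self.bounds[1][b2], self.bounds[1][b2 + 1]),
                (self.bounds[2][b3], self.bounds[2][b3 + 1])]

    def counts_per_block(self, positions):
        owners = self.assign(positions)
        return np.bincount(owners, minlength=self.n_blocks)


def midpoint_owner(grid: BlockGrid, xi, xj):
    """Flat block id owning the pair (i, j): the block containing the
    midpoint of the minimum-image segment anchored at atom i."""
    dr = grid.box.minimum_image(np.atleast_2d(xi) - np.atleast_2d(xj))
    mid = grid.box.wrap(np.atleast_2d(xi) - 0.5 * dr)
    return int(grid.assign(mid)[0])


def midpoint_owners(grid: BlockGrid, positions, pairs):
    """Vectorised midpoint ownership for a half pair list."""
    pi, pj = pairs
    dr = grid.box.minimum_image(positions[pi] - positions[pj])
    mid = grid.box.wrap(positions[pi] - 0.5 * dr)
    return grid.assign(mid)


def halo_atoms(grid: BlockGrid, flat_id, positions, halo):
    """Atom indices a block must import: non-owned atoms whose wrapped
    coordinate lies within ``halo`` of the block along every axis (the
    rectangular-shell approximation of the midpoint import region)."""
    L = grid.box.lengths
    if halo > grid.box.min_edge / 2.0:
        raise ConfigurationError("halo distance exceeds half the box")
    pos = grid.box.wrap(positions)
    bounds = grid.block_bounds(flat_id)
    inside_all = np.ones(pos.shape[0], dtype=bool)
    owned = grid.assign(positions) == flat_id
    for ax, (lo, hi) in enumerate(bounds):
        x = pos[:, ax]
        # distance from x to the interval [lo, hi) on a ring of length L
        d_lo = np.mod(lo - x, L[ax])
        d_hi = np.mod(x - hi, L[ax])
        dist = np.where((x >= lo) & (x < hi), 0.0, np.minimum(d_lo, d_hi))
        inside_all &= dist <= halo
    return np.nonzero(inside_all & ~owned)[0]


def partition_pairs(grid: BlockGrid, positions, pairs):
    """Split a half pair list into per-block midpoint-owned sublists."""
    owners = midpoint_owners(grid, positions, pairs)
    pi, pj = pairs
    out = {}
    for b in range(grid.n_blocks):
        sel = owners == b
        if np.any(sel):
            out[b] = (pi[sel], pj[sel])
    return out


def rebalance_blocks(grid: BlockGrid, positions, max_iterations=4):
    """Iteratively move interval planes toward per-axis coordinate quantiles
    so blocks hold similar atom counts; never worsens the max/min ratio."""

    def ratio(g):
        c = g.counts_per_block(positions)
        lo = max(int(c.min()), 1)
        return c.max() / lo

    best = grid
    best_ratio = ratio(grid)
    pos = grid.box.wrap(positions)
    for _ in range(max_iterations):
        new_bounds = []
        for ax in range(3):
            nb = best.counts[ax]
            if nb == 1:
                new_bounds.append(best.bounds[ax].copy())
                continue
            qs = np.quantile(pos[:, ax], np.linspace(0, 1, nb + 1)[1:-1])
            b = np.concatenate([[0.0], np.sort(qs), [grid.box.lengths[ax]]])
            # enforce strictly increasing planes
            for k in range(1, len(b)):
                b[k] = max(b[k], b[k - 1] + 1e-9)
            b[-1] = grid.box.lengths[ax]
            new_bounds.append(b)
        cand = BlockGrid(grid.box, best.counts, new_bounds)
        r = ratio(cand)
        if r < best_ratio - 1e-12:
            best, best_ratio = cand, r
        else:
            break
    return best


def block_report(grid: BlockGrid, positions, halo):
    """Plain-text diagnostic table of per-block atom counts and halo sizes."""
    lines = ["block  atoms  halo"]
    counts = grid.counts_per_block(positions)
    for b in range(grid.n_blocks):
        h = len(halo_atoms(grid, b, positions, halo))
        lines.append(f"{b:5d}  {int(counts[b]):5d}  {h:4d}")
    return "\n".join(lines)
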