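"""O(N) linked-cell neighbour search with a Verlet skin.

The cell grid subdivides the periodic box into cells of edge >= (cutoff +
skin)/1 per axis (at least one cell); pair enumeration visits each unordered
cell pair once, yielding a half neighbour list.  Lists stay valid while no
atom has moved more than skin/2 since the last rebuild.
"""

from __future__ import annotations

import numpy as np

from .system import ConfigurationError


class CellGrid:
    """Cell->atom buckets for one configuration."""

    def __init__(self, positions, box, cutoff):
        if box.periodic:
            box.check_cutoff(cutoff)
        self.box = box
        self.cutoff = float(cutoff)
        L = box.lengths if box.periodic else (
            positions.max(axis=0) - positions.min(axis=0) + 2 * cutoff + 1e-9)
        self.origin = (np.zeros(3) if box.periodic
                       else positions.min(axis=0) - cutoff)
        nc = np.maximum(np.floor(L / cutoff).astype(int), 1)
        self.ncells = nc
        self.cell_edge = L / nc
        pos = box.wrap(positions) if box.periodic else positions
        ci = np.floor((pos - self.origin) / self.cell_edge).astype(int)
        ci = np.minimum(np.maximum(ci, 0), nc - 1) if not box.periodic else \
            np.mod(ci, nc)
        self.cell_index = ci
        flat = (ci[:, 0] * nc[1] + ci[:, 1]) * nc[2] + ci[:, 2]
        self.buckets = {}
        for a, f in enumerate(flat):
            self.buckets.setdefault(int(f), []).append(a)

    def occupied(self):
        return self.buckets

    def _neighbor_cells(self, cx, cy, cz):
        nc = self.ncells
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    x, y, z = cx + dx, cy + dy, cz + dz
                    if self.box.periodic:
                        x %= nc[0]
                        y %= nc[1]
                        z %= nc[2]
                    elif not (0 <= x < nc[0] and 0 <= y < nc[1]
                              and 0 <= z < nc[2]):
                        continue
                    yield (x * nc[1] + y) * nc[2] + z


class NeighborList:
    """Half list of within-cutoff(+skin) pairs under minimum image."""

    def __init__(self, positions, box, cutoff, skin=1.0):
        self.cutoff = float(cutoff)
        self.skin = float(skin)
        self.box = box
        self.rebuild_count = 0
        self.rebuild(positions)

    def rebuild(self, positions):
        box = self.box
        rlist = self.cutoff + self.skin
        if box.periodic and rlist > box.min_edge / 2.0:
            raise ConfigurationError(
                f"cutoff+skin {rlist:.2f} Å exceeds half box edge")
        n = positions.shape[0]
        if n > 400 or not box.periodic:
            pi, pj = self._pairs_cells(positions, rlist)
        else:
            pi, pj = self._pairs_n2(positions, rlist)
        self.pairs = (pi, pj)
        self._ref_positions = positions.copy()
        self.rebuild_count += 1

    def _pairs_n2(self, positions, rlist):
        n = positions.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        dr = self.box.minimum_image(positions[ii] - positions[jj])
        keep = np.einsum("ka,ka->k", dr, dr) <= rlist * rlist
        return ii[keep].astype(np.int64), jj[keep].astype(np.int64)

    def _pairs_cells(self, positions, rlist):
        grid = CellGrid(positions, self.box, rlist)
        seen_cellpairs = set()
        out_i, out_j = [], []
        nc = grid.ncells
        r2 = rlist * rlist
        for f, atoms in grid.buckets.items():
            cx, cy, cz = f // (nc[1] * nc[2]), (f // nc[2]) % nc[1], f % nc[2]
            for g in grid._neighbor_cells(cx, cy, cz):
                if g not in grid.buckets:
                    continue
                key = (f, g) if f <= g else (g, f)
                if key in seen_cellpairs:
                    continue
                seen_cellpairs.add(key)
                batoms = grid.buckets[g]
                if f == g:
                    arr = np.array(atoms)
                    for u in range(len(arr)):
                        a = arr[u]
                        dr = self.box.minimum_image(
                            positions[arr[u + 1:]] - positions[a])
                        d2 = np.einsum("ka,ka->k", dr, dr)
                        for b in arr[u + 1:][d2 <= r2]:
                            out_i.append(min(a, b))
                            out_j.append(max(a, b))
                else:
                    aarr = np.array(atoms)
                    barr = np.array(batoms)
                    dr = self.box.minimum_image(
                        positions[barr][None, :, :] - positions[aarr][:, None, :])
                    d2 = np.einsum("uka,uka->uk", dr, dr)
                    for u, k in zip(*np.nonzero(d2 <= r2)):
                        a, b = int(aarr[u]), int(barr[k])
                        out_i.append(min(a, b))
                        out_j.append(max(a, b))
        if not out_i:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        pi = np.array(out_i, dtype=np.int64)
        pj = np.array(out_j, dtype=np.int64)
        order = np.lexsort((pj, pi))
        return pi[order], pj[order]

    def needs_rebuild(self, positions):
        dr = self.box.minimum_image(positions - self._ref_positions)
        max_disp = np.sqrt(np.max(np.sum(dr * dr, axis=1))) if len(dr) else 0.0
        return max_disp > self.skin / 2.0

    def update(self, positions):
        if self.needs_rebuild(positions):
            self.rebuild(positions)

    def within_cutoff(self, positions):
        """Pairs of the stored list currently inside the bare cutoff."""
        pi, pj = self.pairs
        dr = self.box.minimum_image(positions[pi] - positions[pj])
        keep = np.einsum("ka,ka->k", dr, dr) <= self.cutoff**2
        return pi[keep], pj[keep]


def build_cell_grid(positions, box, cutoff):
    """Spec surface: construct the linked-cell grid."""
    return CellGrid(positions, box, cutoff)


def build_neighbor_lists(positions, box, cutoff, skin=1.0):
    """Spec surface: half neighbour list with the given cutoff and skin."""
    return NeighborList(positions, box, cutoff, skin)
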