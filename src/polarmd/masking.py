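"""Bonded-neighbour masking: classify pairs by shortest bond-path distance
(1-2, 1-3, 1-4, 1-5) and expose a sparse symmetric scale lookup.

Pairs further than four bonds apart are absent from the lookup and carry the
implicit scale 1.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bond_distance_classes(n_sites: int, bonds: np.ndarray, max_sep: int = 4) -> dict:
    """Breadth-first bond-path distances up to ``max_sep`` bonds.

    Returns {(i, j): separation} with i < j and separation in 1..max_sep,
    where separation 1 means a 1-2 pair.
    """
    adj = [[] for _ in range(n_sites)]
    for i, j in np.asarray(bonds, dtype=int).reshape(-1, 2):
        adj[i].append(j)
        adj[j].append(i)
    out = {}
    for s in range(n_sites):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            if dist[u] >= max_sep:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for v, d in dist.items():
            if v > s and d >= 1:
                out[(s, v)] = d
    return out


class MaskingTable:
    """Sparse pairwise scale-factor lookup built from connectivity.

    ``scales`` maps separation class (2 for 1-2 pairs, ..., 5 for 1-5 pairs)
    to a multiplicative factor; unlisted pairs scale by 1.
    """

    def __init__(self, n_sites: int, bonds: np.ndarray, scales: dict):
        self.n_sites = n_sites
        self.scales = dict(scales)
        self._pairs = {}
        for (i, j), d in bond_distance_classes(n_sites, bonds).items():
            cls = d + 1                      # separation 1 bond -> class "1-2"
            if cls in self.scales:
                self._pairs[(i, j)] = float(self.scales[cls])

    def scale(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self._pairs.get((i, j), 1.0)

    def items(self):
        return self._pairs.items()

    def __len__(self):
        return len(self._pairs)

    def scale_array(self, pairs_i: np.ndarray, pairs_j: np.ndarray) -> np.ndarray:
        """Vector of scales for arrays of pair indices."""
        out = np.ones(len(pairs_i))
        for k in range(len(pairs_i)):
            out[k] = self.scale(int(pairs_i[k]), int(pairs_j[k]))
        return out

    def nonunit_pairs(self):
        """(i, j, scale) arrays for pairs whose scale differs from 1."""
        if not self._pairs:
            return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                    np.zeros(0))
        ii, jj, ss = [], [], []
        for (i, j), s in sorted(self._pairs.items()):
            ii.append(i)
            jj.append(j)
            ss.append(s)
        return np.array(ii), np.array(jj), np.array(ss)


def build_masking(n_sites: int, bonds: np.ndarray, scales: dict) -> MaskingTable:
    """Spec surface: build the sparse pairwise scale lookup."""
    return MaskingTable(n_sites, bonds, scales)
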