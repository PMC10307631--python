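"""Hexagonal spot-array geometry.

Spatial capture arrays (Visium-style) place spots on a hexagonal lattice in
which every interior spot has six equidistant neighbours.  Internally we work
in axial coordinates ``(q, r)``; on disk coordinates are stored in the
array-style even-q offset convention ``(array_row, array_col)`` so the text
sidecars look like the vendor's ``tissue_positions`` tables.
"""

from __future__ import annotations

import numpy as np

#: the six axial direction vectors (dq, dr)
AXIAL_DIRECTIONS = np.array(
    [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)], dtype=int
)


def axial_to_offset(q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axial ``(q, r)`` -> even-q offset ``(row, col)``."""
    q = np.asarray(q, dtype=int)
    r = np.asarray(r, dtype=int)
    col = q
    row = r + (q + (q & 1)) // 2
    return row, col


def offset_to_axial(row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Even-q offset ``(row, col)`` -> axial ``(q, r)``; inverse of
    :func:`axial_to_offset`."""
    row = np.asarray(row, dtype=int)
    col = np.asarray(col, dtype=int)
    q = col
    r = row - (col + (col & 1)) // 2
    return q, r


def hex_grid(n_spots: int) -> tuple[np.ndarray, np.ndarray]:
    """Return axial coordinates for ``n_spots`` filling a roughly square patch."""
    side = int(np.ceil(np.sqrt(n_spots)))
    qs, rs = [], []
    for row in range(side + 1):
        for col in range(side):
            q, r = offset_to_axial(np.array(row), np.array(col))
            qs.append(int(q))
            rs.append(int(r))
            if len(qs) == n_spots:
                return np.array(qs), np.array(rs)
    return np.array(qs[:n_spots]), np.array(rs[:n_spots])


def neighbor_sets(q: np.ndarray, r: np.ndarray) -> list[set[int]]:
    """For each spot, the set of indices of its (up to six) lattice neighbours.

    Invariant under translation of the grid: only coordinate differences enter.
    """
    q = np.asarray(q, dtype=int)
    r = np.asarray(r, dtype=int)
    index = {(int(qq), int(rr)): i for i, (qq, rr) in enumerate(zip(q, r))}
    if len(index) != len(q):
        raise ValueError("duplicate hex coordinates")
    out: list[set[int]] = []
    for qq, rr in zip(q, r):
        nb = set()
        for dq, dr in AXIAL_DIRECTIONS:
            j = index.get((int(qq + dq), int(rr + dr)))
            if j is not None:
                nb.add(j)
        out.append(nb)
    return out
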