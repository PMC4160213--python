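"""Topology-preserving 3D curve thinning.

Iterative deletion of *simple points* — voxels whose removal changes
neither the 26-connected foreground components, nor the 6-connected
background components, nor any loops/cavities — from the six directional
borders of the mask in a fixed order, until stable.  Line-end voxels
(exactly one foreground neighbour) are protected, which leaves a centred
one-voxel-wide curve skeleton for tubular shapes.

Simple-point characterisation (topological numbers):

* C*  = number of 26-connected components of the foreground within the
  26-neighbourhood (centre excluded);
* C-bar = number of 6-connected components of the background within the
  18-neighbourhood that touch a face neighbour of the centre.

The point is simple iff C* == 1 and C-bar == 1.

Within one directional sub-iteration, candidates are processed per voxel
parity class (z%2, y%2, x%2): voxels of equal parity are never
26-adjacent, so deleting a batch simultaneously cannot invalidate another
batch member's simple-point status — parallel deletion is exactly
equivalent to sequential deletion, and the result is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["thin_mask"]

# neighbourhood bookkeeping ---------------------------------------------------

_OFF26 = np.array([(dz, dy, dx)
                   for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                   if (dz, dy, dx) != (0, 0, 0)], dtype=np.int64)
_N18_SEL = np.array([np.abs(o).sum() <= 2 for o in _OFF26])          # 18-neighbourhood
_FACE_SEL = np.array([np.abs(o).sum() == 1 for o in _OFF26])          # 6 face neighbours

def _adjacency(offsets: np.ndarray, max_linf: int, max_l1: int) -> np.ndarray:
    n = len(offsets)
    A = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.abs(offsets[i] - offsets[j])
            if d.max() <= max_linf and d.sum() <= max_l1:
                A[i, j] = True
    return A

_ADJ26 = _adjacency(_OFF26, 1, 3)                      # 26-adjacency among the 26 cells
_ADJ6_18 = _adjacency(_OFF26, 1, 1) & np.outer(_N18_SEL, _N18_SEL)
_N18_IDX = np.nonzero(_N18_SEL)[0]
_FACE_IDX = np.nonzero(_FACE_SEL)[0]

# directional order: U, D, N, S, W, E about the (z, y, x) axes
_DIRECTIONS = np.array([(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0),
                        (0, 0, -1), (0, 0, 1)], dtype=np.int64)

_PROP_ITers = 10  # label-propagation sweeps; N26 graph diameter is < 10


def _count_components(present: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Number of connected components of `present` cells (N, k) under the
    fixed adjacency `adj` (k, k), vectorised over N neighbourhoods."""
    n, k = present.shape
    big = k + 1
    labels = np.where(present, np.arange(k)[None, :], big)
    for _ in range(_PROP_ITers):
        # min label over adjacent present cells
        neigh = np.where(adj[None, :, :] & present[:, None, :], labels[:, None, :], big)
        new = np.minimum(labels, neigh.min(axis=2))
        new = np.where(present, new, big)
        if np.array_equal(new, labels):
            break
        labels = new
    roots = (labels == np.arange(k)[None, :]) & present
    return roots.sum(axis=1), labels


def _simple_points(nb: np.ndarray) -> np.ndarray:
    """Simple-point test for N neighbourhoods given as (N, 26) foreground
    flags (centre excluded)."""
    c_star, _ = _count_components(nb, _ADJ26)
    bg18 = ~nb[:, _N18_IDX]
    _, labels18 = _count_components(bg18, _ADJ6_18[np.ix_(_N18_IDX, _N18_IDX)])
    # components that touch a face neighbour of the centre
    face_pos = np.searchsorted(_N18_IDX, _FACE_IDX)
    face_labels = np.where(bg18[:, face_pos], labels18[:, face_pos], len(_N18_IDX) + 1)
    k18 = len(_N18_IDX)
    touch = np.zeros(nb.shape[0], dtype=np.int64)
    for r in range(k18):
        touch += (face_labels == r).any(axis=1)
    return (c_star == 1) & (touch == 1)


def _gather_neighborhoods(padded: np.ndarray, coords: np.ndarray) -> np.ndarray:
    out = np.empty((len(coords), 26), dtype=bool)
    z, y, x = coords[:, 0] + 1, coords[:, 1] + 1, coords[:, 2] + 1
    for i, (dz, dy, dx) in enumerate(_OFF26):
        out[:, i] = padded[z + dz, y + dy, x + dx]
    return out


_POW2 = (1 << np.arange(26)).astype(np.int64)
_SIMPLE_CACHE: dict[int, bool] = {}


def _simple_points_cached(nb: np.ndarray) -> np.ndarray:
    """Memoised simple-point test: neighbourhood configurations repeat
    heavily in structured masks, so each distinct 26-bit pattern is
    evaluated once per process."""
    keys = nb @ _POW2
    uniq, first, inv = np.unique(keys, return_index=True, return_inverse=True)
    known = np.array([_SIMPLE_CACHE.get(int(k), -1) for k in uniq], dtype=np.int8)
    missing = np.nonzero(known < 0)[0]
    if missing.size:
        res = _simple_points(nb[first[missing]])
        known[missing] = res
        for k, r in zip(uniq[missing], res):
            _SIMPLE_CACHE[int(k)] = bool(r)
    return known[inv].astype(bool)


def thin_mask(mask: np.ndarray, max_iterations: int = 10_000) -> np.ndarray:
    """Thin a 3D boolean mask to a one-voxel-wide curve skeleton."""
    mask = np.asarray(mask) > 0
    padded = np.pad(mask, 1).copy()
    inner = padded[1:-1, 1:-1, 1:-1]  # view: writes update `padded`

    zz, yy, xx = np.indices(mask.shape, sparse=True)
    parity = ((zz % 2) * 4 + (yy % 2) * 2 + (xx % 2)).astype(np.int8)
    parity = np.broadcast_to(parity, mask.shape)

    for _ in range(max_iterations):
        any_deleted = False
        for d in _DIRECTIONS:
            # border in direction d: foreground with background d-neighbour
            shifted = padded[1 + d[0]: padded.shape[0] - 1 + d[0],
                             1 + d[1]: padded.shape[1] - 1 + d[1],
                             1 + d[2]: padded.shape[2] - 1 + d[2]]
            border = inner & ~shifted
            if not border.any():
                continue
            for p in range(8):
                cand = np.argwhere(border & (parity == p) & inner)
                if len(cand) == 0:
                    continue
                nb = _gather_neighborhoods(padded, cand)
                nn = nb.sum(axis=1)
                keep_out = (nn <= 1)  # line ends and isolated voxels survive
                test = ~keep_out
                if not test.any():
                    continue
                simple = np.zeros(len(cand), dtype=bool)
                simple[test] = _simple_points_cached(nb[test])
                if simple.any():
                    dz, dy, dx = cand[simple].T
                    inner[dz, dy, dx] = False
                    any_deleted = True
        if not any_deleted:
            break
    return inner.copy()
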