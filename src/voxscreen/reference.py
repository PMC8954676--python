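"""Brute-force reference implementations used for validation.

These deliberately re-derive results by the most transparent route
available — dense-array breadth-first search, all-pairs similarity loops,
hand conv-arithmetic — and share no code with the production paths they
check. The test suite and the acceptance script compare the two routes;
the implementations here are never used by the pipeline itself.
"""

from __future__ import annotations

from collections import deque

import numpy as np

__all__ = [
    "flood_reference",
    "butina_reference",
    "shape_chain_reference",
    "spearman",
]


def flood_reference(protein_xyz: np.ndarray, seed: np.ndarray, *,
                    spacing: float = 1.0, occlusion_radius: float = 2.0,
                    max_radius: float = 12.0, burial_min_neighbors: int = 8,
                    burial_radius: float = 8.0,
                    connectivity: int = 6) -> set[tuple[int, int, int]]:
    """Dense-lattice BFS flood with direct distance computations.

    Precomputes open/buried masks over the whole bounding lattice by
    explicit all-pairs distances (no spatial index), then runs BFS.
    """
    protein_xyz = np.asarray(protein_xyz, dtype=float)
    seed = np.asarray(seed, dtype=float)
    r = int(np.ceil(max_radius / spacing))
    rng = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    centers = seed[None, :] + spacing * np.stack(
        [ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d = np.linalg.norm(centers[:, None, :] - protein_xyz[None, :, :], axis=2)
    open_mask = (d.min(axis=1) >= occlusion_radius).reshape(ii.shape)
    buried_mask = ((d < burial_radius).sum(axis=1)
                   >= burial_min_neighbors).reshape(ii.shape)
    within = (np.linalg.norm(centers - seed[None, :], axis=1)
              <= max_radius).reshape(ii.shape)
    good = open_mask & buried_mask & within

    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]
    else:
        offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]

    start = (r, r, r)
    if not good[start]:
        raise ValueError("seed voxel is not open/buried in the reference")
    seen = {start}
    out = {(0, 0, 0)}
    q = deque([start])
    n = 2 * r + 1
    while q:
        cur = q.popleft()
        for off in offs:
            nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if nxt in seen:
                continue
            if not all(0 <= v < n for v in nxt):
                continue
            seen.add(nxt)
            if good[nxt]:
                out.add((nxt[0] - r, nxt[1] - r, nxt[2] - r))
                q.append(nxt)
    return out


def butina_reference(fps: dict[str, np.ndarray], cutoff: float
                     ) -> list[tuple[str, list[str]]]:
    """Naive all-pairs Butina clustering over boolean bit arrays.

    Same published procedure, written with explicit Python loops:
    neighbor counts by pairwise Tanimoto, descending-count order with
    lexicographic tie-break, greedy sphere exclusion.
    """
    ids = sorted(fps)
    nbrs: dict[str, set[str]] = {i: set() for i in ids}
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            fa, fb = fps[a].astype(bool), fps[b].astype(bool)
            union = int(np.logical_or(fa, fb).sum())
            sim = 1.0 if union == 0 else int(np.logical_and(fa, fb).sum()) / union
            if sim >= cutoff:
                nbrs[a].add(b)
                nbrs[b].add(a)
    order = sorted(ids, key=lambda i: (-len(nbrs[i]), i))
    assigned: set[str] = set()
    clusters = []
    for rep in order:
        if rep in assigned:
            continue
        members = [rep] + sorted(m for m in nbrs[rep] if m not in assigned)
        assigned.update(members)
        clusters.append((rep, sorted(members)))
    return clusters


def shape_chain_reference(n: int, channels: int = 14) -> dict[str, object]:
    """Hand conv-arithmetic for the default scoring stack on an n^3 grid.

    Valid convolutions shrink each edge by (kernel - 1); 2x2x2 pooling
    halves it (floor). Returns every intermediate edge length and the
    flattened feature count entering the dense head.
    """
    edges = [n]
    e = n
    for step in ("conv3", "conv3", "pool", "conv3", "conv3", "pool", "conv2"):
        if step == "conv3":
            e = e - 2
        elif step == "conv2":
            e = e - 1
        else:
            e = e // 2
        if e < 1:
            raise ValueError(f"edge collapsed at step {step}")
        edges.append(e)
    return {"edges": edges, "flat_features": 64 * e ** 3}


def spearman(a, b) -> float:
    """Spearman rank correlation via explicit ranking (average ties)."""
    from scipy.stats import rankdata
    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra ** 2).sum() * (rb ** 2).sum()))
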