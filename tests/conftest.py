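"""Shared fixtures and independent reference implementations.

The reference implementations here deliberately avoid the package's fast
paths: graphs are coloured by explicit breadth-first search, SHMs are
evaluated by nested dictionary lookup on bit tuples, and conflict edges are
found by scanning all pairs of defined cells against the equivalence
definition directly.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from treeshm.core import (
    GroundTruthSHM,
    LabelTable,
    TreeStructure,
    code_to_bits,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bfs_two_coloring(n_vertices: int, edges: set[tuple[int, int]]):
    """Reference 2-colouring by BFS, anchored at the smallest vertex of each
    component (colour 0).  Returns (colors, component_ids) or None if some
    edge joins two equal colours (odd cycle)."""
    adj: dict[int, list[int]] = {v: [] for v in range(n_vertices)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    colors = [-1] * n_vertices
    comp = [-1] * n_vertices
    for start in range(n_vertices):
        if colors[start] != -1:
            continue
        colors[start] = 0
        comp[start] = start
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if colors[w] == -1:
                    colors[w] = 1 - colors[u]
                    comp[w] = start
                    queue.append(w)
                elif colors[w] == colors[u]:
                    return None
    return np.array(colors), np.array(comp)


def naive_conflict_edges(table: LabelTable, structure: TreeStructure):
    """Edge sets per module by scanning every pair of defined cells against
    the equivalent-i-extension definition on bit tuples."""
    cells = [
        (code_to_bits(int(c), structure.d), int(table.values()[c]))
        for c in table.defined_codes()
    ]
    edge_sets: list[set[tuple[int, int]]] = [set() for _ in range(structure.k)]
    for i in range(1, structure.k + 1):
        s = structure.block_slice(i)
        for xa, la in cells:
            for xb, lb in cells:
                if la == 0 and lb == 1:
                    if xa[: s.start] + xa[s.stop :] == xb[: s.start] + xb[s.stop :]:
                        u = int("".join(map(str, xa[s])), 2)
                        v = int("".join(map(str, xb[s])), 2)
                        if u != v:
                            edge_sets[i - 1].add((min(u, v), max(u, v)))
    return edge_sets


def nested_lookup_eval(m: GroundTruthSHM, bits: tuple[int, ...]) -> int:
    """Reference SHM evaluation: dictionary lookups on sliced bit tuples."""
    module_maps = []
    for i, n_i in enumerate(m.structure.block_sizes, start=1):
        table = {}
        for v in range(1 << n_i):
            table[code_to_bits(v, n_i)] = int(m.module_tables[i - 1][v])
        module_maps.append(table)
    out_map = {}
    for z in range(1 << m.structure.k):
        out_map[code_to_bits(z, m.structure.k)] = int(m.output_table[z])
    inter = []
    pos = 0
    for i, n_i in enumerate(m.structure.block_sizes):
        inter.append(module_maps[i][bits[pos : pos + n_i]])
        pos += n_i
    return out_map[tuple(inter)]


def all_completions_possible(structure: TreeStructure, codes, labels) -> np.ndarray:
    """All-completions oracle for k = 2 structures.

    Enumerates every (f_1, f_2, g) triple consistent with the defined cells
    and returns ``poss[label, cell]``: whether some consistent completion
    assigns ``label`` to ``cell``.
    """
    if structure.k != 2:
        raise ValueError("oracle supports k = 2 only")
    n1, n2 = structure.block_sizes
    d = n1 + n2
    M1, M2, MG = 1 << (1 << n1), 1 << (1 << n2), 1 << 4
    F2 = ((np.arange(M2)[:, None] >> np.arange(1 << n2)[None, :]) & 1).astype(np.int8)
    G = ((np.arange(MG)[:, None] >> np.arange(4)[None, :]) & 1).astype(np.int8)
    codes = np.asarray(codes)
    labels = np.asarray(labels)
    b1, b2 = codes >> n2, codes & ((1 << n2) - 1)
    allc = np.arange(1 << d)
    a1, a2 = allc >> n2, allc & ((1 << n2) - 1)
    poss = np.zeros((2, 1 << d), dtype=bool)
    for m1 in range(M1):
        f1 = (m1 >> np.arange(1 << n1)) & 1
        z = 2 * f1[b1][None, :] + F2[:, b2]  # (M2, n_defined)
        ok = (G[:, z] == labels[None, None, :]).all(-1)  # (MG, M2)
        if not ok.any():
            continue
        z_all = 2 * f1[a1][None, :] + F2[:, a2]
        pred_all = G[:, z_all]  # (MG, M2, 2^d)
        for lab in (0, 1):
            poss[lab] |= ((pred_all == lab) & ok[:, :, None]).any((0, 1))
    return poss
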