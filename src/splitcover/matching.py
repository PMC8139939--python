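"""Maximum cardinality matching in general graphs.

Blossom-contraction augmenting-path search (Edmonds) with a greedy
initial matching. Written for the sparse, near-perfectly-matchable
compatibility graphs this package produces, where the number of
augmentation phases after greedy initialization is small; each phase is a
single BFS with on-the-fly blossom contraction.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, Hashable, Iterable, List, Sequence, Tuple

__all__ = ["maximum_matching_adjacency", "maximum_matching"]


def maximum_matching_adjacency(adj: Sequence[Sequence[int]]) -> List[int]:
    """Maximum cardinality matching on vertices ``0..len(adj)-1``.

    Returns ``mate`` with ``mate[v]`` the partner of ``v`` or -1.
    """
    n = len(adj)
    mate = [-1] * n

    # Greedy maximal matching: cheap, and leaves few exposed vertices on
    # regular graphs, so few augmentation phases remain.
    for v in range(n):
        if mate[v] == -1:
            for u in adj[v]:
                if mate[u] == -1:
                    mate[v] = u
                    mate[u] = v
                    break

    parent = [-1] * n
    base = list(range(n))
    in_queue = [False] * n

    def lca(a: int, b: int) -> int:
        seen = [False] * n
        while True:
            a = base[a]
            seen[a] = True
            if mate[a] == -1:
                break
            a = parent[mate[a]]
        while True:
            b = base[b]
            if seen[b]:
                return b
            b = parent[mate[b]]

    def mark_path(v: int, b: int, child: int, in_blossom: List[bool]) -> None:
        while base[v] != b:
            in_blossom[base[v]] = True
            in_blossom[base[mate[v]]] = True
            parent[v] = child
            child = mate[v]
            v = parent[mate[v]]

    def find_augmenting_path(root: int) -> int:
        for i in range(n):
            parent[i] = -1
            base[i] = i
            in_queue[i] = False
        in_queue[root] = True
        queue = deque([root])
        while queue:
            v = queue.popleft()
            for to in adj[v]:
                if base[v] == base[to] or mate[v] == to:
                    continue
                if to == root or (mate[to] != -1 and parent[mate[to]] != -1):
                    # An odd cycle (blossom): contract it to its base.
                    cur_base = lca(v, to)
                    in_blossom = [False] * n
                    mark_path(v, cur_base, to, in_blossom)
                    mark_path(to, cur_base, v, in_blossom)
                    for i in range(n):
                        if in_blossom[base[i]]:
                            base[i] = cur_base
                            if not in_queue[i]:
                                in_queue[i] = True
                                queue.append(i)
                elif parent[to] == -1:
                    parent[to] = v
                    if mate[to] == -1:
                        return to  # augmenting path found
                    in_queue[mate[to]] = True
                    queue.append(mate[to])
        return -1

    for v in range(n):
        if mate[v] == -1:
            end = find_augmenting_path(v)
            if end != -1:
                # Flip matched/unmatched edges back along the path.
                u = end
                while u != -1:
                    pv = parent[u]
                    ppv = mate[pv]
                    mate[u] = pv
                    mate[pv] = u
                    u = ppv
    return mate


def maximum_matching(
    vertices: Sequence[Hashable], edges: Iterable[Tuple[Hashable, Hashable]]
) -> Dict[Hashable, Hashable]:
    """Maximum cardinality matching over arbitrary hashable vertices.

    Returns a symmetric mate map containing only matched vertices.
    """
    index = {v: i for i, v in enumerate(vertices)}
    adj: List[List[int]] = [[] for _ in vertices]
    for a, b in edges:
        ia, ib = index[a], index[b]
        if ia != ib:
            adj[ia].append(ib)
            adj[ib].append(ia)
    mate = maximum_matching_adjacency(adj)
    out: Dict[Hashable, Hashable] = {}
    for v, i in index.items():
        if mate[i] != -1:
            out[v] = vertices[mate[i]]
    return out
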