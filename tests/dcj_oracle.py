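"""Independent breadth-first-search oracle for the DCJ distance.

A genome state is the set of its adjacencies over signed gene extremities
(every extremity paired: the all-circular state space).  One DCJ operation
replaces two adjacencies {p,q}, {r,s} by {p,r},{q,s} or {p,s},{q,r}.  The
oracle knows nothing about cycle counting; it literally searches the
operation graph.
"""

from collections import deque

from mitorder.gene_order import GeneOrder, _extremity_adjacencies


def state_of(g: GeneOrder) -> frozenset:
    return frozenset(frozenset(pair) for pair in _extremity_adjacencies(g))


def neighbors(state: frozenset):
    adjacencies = list(state)
    for i in range(len(adjacencies)):
        for j in range(i + 1, len(adjacencies)):
            p, q = tuple(adjacencies[i])
            r, s = tuple(adjacencies[j])
            rest = state - {adjacencies[i], adjacencies[j]}
            yield rest | {frozenset((p, r)), frozenset((q, s))}
            yield rest | {frozenset((p, s)), frozenset((q, r))}


def bfs_distance_map(g1: GeneOrder) -> dict:
    """Distances from g1's state to every reachable all-circular state."""
    start = state_of(g1)
    dist = {start: 0}
    frontier = deque([start])
    while frontier:
        state = frontier.popleft()
        for nxt in neighbors(state):
            if nxt not in dist:
                dist[nxt] = dist[state] + 1
                frontier.append(nxt)
    return dist


def bfs_dcj_distance(g1: GeneOrder, g2: GeneOrder, max_depth: int = 10) -> int:
    start, goal = state_of(g1), state_of(g2)
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        state, depth = frontier.popleft()
        if depth >= max_depth:
            continue
        for nxt in neighbors(state):
            if nxt == goal:
                return depth + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, depth + 1))
    raise RuntimeError("goal not reached within max_depth")
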