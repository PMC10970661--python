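"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive pure Python (loops, dicts, sorting) and
shares no code path with the package.
"""

from __future__ import annotations

import math


def brute_nearest(cost_of: dict[str, float]) -> tuple[str, float]:
    """Exhaustive argmin with lexicographic tie-break on the facility id."""
    best_id, best_cost = None, math.inf
    for fid in sorted(cost_of):
        c = cost_of[fid]
        if c < best_cost:
            best_id, best_cost = fid, c
    return best_id, best_cost


def brute_zap(cost_of: dict[str, float], radius: float) -> tuple[str, ...]:
    """Inclusive threshold filter."""
    return tuple(sorted(f for f, c in cost_of.items() if c <= radius))


def brute_weighted_mean(costs, weights) -> float:
    total = sum(weights)
    if total == 0:
        return sum(costs) / len(costs)
    return sum(c * w for c, w in zip(costs, weights)) / total


def brute_pressure(area_pop: dict[str, float],
                   costs: dict[str, dict[str, float]]) -> dict[str, float]:
    """Assign each area's population to its brute-force nearest facility."""
    out: dict[str, float] = {}
    for aid, pop in area_pop.items():
        fid, _ = brute_nearest(costs[aid])
        out[fid] = out.get(fid, 0.0) + pop
    return out


def brute_deciles_quantile(values) -> list[int]:
    """Decile labels from boundaries interpolated in exact rational arithmetic,
    1 = highest values. Boundaries sit at quantiles 0.1..0.9 of the sorted
    values (linear interpolation at position (n-1)q); strict comparison sends
    boundary ties to the better class."""
    from fractions import Fraction

    s = sorted(values)
    n = len(s)
    cuts = []
    for q in range(1, 10):  # ascending Q10 .. Q90
        pos = Fraction((n - 1) * q, 10)
        f = int(pos)
        frac = pos - f
        cut = Fraction(s[f])
        if frac:
            cut += frac * (Fraction(s[f + 1]) - Fraction(s[f]))
        cuts.append(cut)
    return [1 + sum(Fraction(v) < c for c in reversed(cuts)) for v in values]


def brute_deciles(values) -> list[int]:
    """Sort-and-slice decile labels, 1 = highest values; assumes distinct values."""
    order = sorted(range(len(values)), key=lambda i: -values[i])
    n = len(values)
    labels = [0] * n
    for rank, i in enumerate(order):
        labels[i] = min(10, rank * 10 // n + 1)
    return labels


def brute_agreement(a: list[int], b: list[int]) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def brute_groupby(values: dict[str, float], unit_of: dict[str, str],
                  stat: str, pops: dict[str, float] | None = None) -> dict[str, float]:
    groups: dict[str, list[str]] = {}
    for aid, unit in unit_of.items():
        groups.setdefault(unit, []).append(aid)
    out = {}
    for unit, members in groups.items():
        v = [values[m] for m in members]
        if stat == "min":
            out[unit] = min(v)
        elif stat == "max":
            out[unit] = max(v)
        elif stat == "mean":
            out[unit] = sum(v) / len(v)
        elif stat == "weighted_mean":
            w = [pops[m] for m in members]
            out[unit] = brute_weighted_mean(v, w)
    return out


def all_simple_path_costs(edges: dict[tuple[str, str], float],
                          source: str, target: str) -> float:
    """Minimum cost over every simple path, by exhaustive DFS enumeration.

    ``edges`` maps directed (u, v) pairs to weights. Returns inf when no path
    exists. Only viable for tiny graphs (<= 8 nodes).
    """
    adj: dict[str, list[tuple[str, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))

    best = math.inf

    def dfs(node: str, cost: float, seen: frozenset):
        nonlocal best
        if node == target:
            best = min(best, cost)
            return
        for nxt, w in adj.get(node, []):
            if nxt not in seen:
                dfs(nxt, cost + w, seen | {nxt})

    dfs(source, 0.0, frozenset([source]))
    return best


def bellman_ford(edges: dict[tuple[str, str], float], nodes: list[str],
                 source: str) -> dict[str, float]:
    """Textbook Bellman-Ford relaxation, independent of any graph library."""
    dist = {n: math.inf for n in nodes}
    dist[source] = 0.0
    for _ in range(len(nodes) - 1):
        for (u, v), w in edges.items():
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
    return dist


def blom_scores_sorted(n: int):
    """Closed-form Blom plotting positions through an independent quantile routine."""
    from statistics import NormalDist

    nd = NormalDist()
    return [nd.inv_cdf((i - 0.375) / (n + 0.25)) for i in range(1, n + 1)]
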