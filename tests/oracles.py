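"""Independent brute-force reimplementations used as test oracles.

These follow the stated clustering and scoring rules naively and share no
code with the implementation under test.
"""

from __future__ import annotations


def oracle_salience(edges: list[tuple[str, str, float]], v: str) -> float:
    return sum(w for a, b, w in edges if v in (a, b))


def oracle_cluster(
    vertices: list[str], edges: list[tuple[str, str, float]], hub_ratio: float
) -> list[tuple[set[str], set[str]]]:
    """Greedy HVS clustering; returns (members, hvs) pairs in creation order."""

    def weight_to(v: str, group: set[str]) -> float:
        total = 0.0
        for a, b, w in edges:
            if a == v and b in group:
                total += w
            elif b == v and a in group:
                total += w
        return total

    order = sorted(vertices, key=lambda v: (-oracle_salience(edges, v), v))
    n_hubs = max(1, round(hub_ratio * len(vertices)))
    clusters: list[tuple[set[str], set[str]]] = []
    for h in order[:n_hubs]:
        scores = [weight_to(h, hvs) for _, hvs in clusters]
        if scores and max(scores) > 0:
            i = scores.index(max(scores))
            clusters[i][0].add(h)
            clusters[i][1].add(h)
        else:
            clusters.append(({h}, {h}))
    for v in order[n_hubs:]:
        scores = [weight_to(v, members) for members, _ in clusters]
        if scores and max(scores) > 0:
            clusters[scores.index(max(scores))][0].add(v)
    return clusters


def oracle_score(
    clusters: list[tuple[set[str], set[str]]], sentence_vertices: set[str]
) -> float:
    total = 0.0
    for members, hvs in clusters:
        votes = 0.0
        for v in sentence_vertices:
            if v in hvs:
                votes += 1.0
            elif v in members:
                votes += 0.5
        total += votes / len(members)
    return total
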