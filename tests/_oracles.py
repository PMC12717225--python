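"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (O(n²) loops, hand-rolled formulas) kept
separate from the package so that agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_radius_edges(xy: np.ndarray, radius: float) -> set[tuple[int, int]]:
    """All unordered index pairs at Euclidean distance <= radius."""
    n = len(xy)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= radius:
                out.add((i, j))
    return out


def brute_force_pair_scores(edges, labels) -> dict[tuple[str, str], int]:
    """Edge count per unordered label pair, looping edge by edge."""
    out: dict[tuple[str, str], int] = {}
    for i, j in edges:
        key = tuple(sorted((labels[i], labels[j])))
        out[key] = out.get(key, 0) + 1
    return out


def fan_triangulation_area(vertices: np.ndarray) -> float:
    """Polygon area as a sum of signed fan triangles from vertex 0."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b, c = v[0], v[i], v[i + 1]
        total += 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    return abs(total)


def winding_inside(point, ring) -> bool:
    """Even-odd crossing-number point-in-ring test."""
    x, y = point
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xc = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xc:
                inside = not inside
    return inside


def winding_inside_with_holes(point, exterior, holes) -> bool:
    """Even-odd over all rings: inside the exterior and outside every hole."""
    inside = winding_inside(point, exterior)
    for h in holes:
        if winding_inside(point, h):
            inside = not inside
    return inside


def step_up_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, written out by hand."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        candidate = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def exhaustive_enrichment_null(edges, labels):
    """Exact permutation distribution of pair scores over all label orders.

    Returns the list of score dicts, one per permutation of the label
    multiset (all n! orderings, so duplicates occur with the right weight).
    """
    nulls = []
    for perm in itertools.permutations(labels):
        nulls.append(brute_force_pair_scores(edges, list(perm)))
    return nulls
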