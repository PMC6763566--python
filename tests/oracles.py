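"""Independent brute-force oracles used to check the fast implementations.

Everything here recomputes a quantity from its definition by exhaustive
enumeration or via a third-party geometric predicate, on purpose ignoring
the vectorized/cumulative shortcuts the package itself uses.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import shapely.geometry as sg


def otsu_exhaustive(values, n_bins: int):
    """Between-class variance at every interior bin edge, by direct search.

    Recomputes the criterion with plain loops over the histogram (no
    cumulative-moment shortcuts).  Returns (best_edge, best_crit, edges,
    crit_per_edge) so a caller can also evaluate the criterion at any other
    candidate edge.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    crit_all = np.empty(n_bins - 1)
    for k in range(1, n_bins):
        n0, n1 = hist[:k].sum(), hist[k:].sum()
        if n0 == 0 or n1 == 0:
            crit_all[k - 1] = 0.0
            continue
        mu0 = float((hist[:k] * centers[:k]).sum()) / n0
        mu1 = float((hist[k:] * centers[k:]).sum()) / n1
        crit_all[k - 1] = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    best = int(np.argmax(crit_all))
    return float(edges[best + 1]), float(crit_all[best]), edges, crit_all


def otsu_attains_maximum(threshold_result, values, n_bins: int, rtol=1e-9) -> bool:
    """True iff the returned threshold's exhaustively recomputed criterion
    equals the exhaustive maximum (to summation-order rounding)."""
    _, best_crit, edges, crit_all = otsu_exhaustive(values, n_bins)
    k = int(np.argmin(np.abs(edges[1:-1] - threshold_result.threshold)))
    if edges[k + 1] != threshold_result.threshold:
        return False
    return bool(np.isclose(crit_all[k], best_crit, rtol=rtol, atol=0.0))


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact p by enumerating every group assignment of the pooled
    values and counting pairwise wins directly (no rank arithmetic)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a, n_b = len(a), len(b)
    u_obs = float((a[:, None] > b[None, :]).sum())
    u_lo = min(u_obs, n_a * n_b - u_obs)
    count = total = 0
    idx = range(len(pooled))
    for combo in combinations(idx, n_a):
        sel = set(combo)
        ga = pooled[list(combo)]
        gb = pooled[[i for i in idx if i not in sel]]
        u = float((ga[:, None] > gb[None, :]).sum())
        total += 1
        if u <= u_lo + 1e-12:
            count += 1
    return min(1.0, 2.0 * count / total)


def pixels_inside(polygon, image_shape) -> np.ndarray:
    """Exhaustive per-pixel membership mask via shapely (boundary included)."""
    poly = sg.Polygon(np.asarray(polygon, dtype=float))
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            mask[y, x] = poly.covers(sg.Point(float(x), float(y)))
    return mask


def random_convex_polygon(rng, center, max_radius, n_vertices=12) -> np.ndarray:
    """Convex polygon: sorted angular samples on a random ellipse."""
    theta = np.sort(rng.uniform(0, 2 * math.pi, size=n_vertices))
    a = rng.uniform(0.5, 1.0) * max_radius
    b = rng.uniform(0.5, 1.0) * max_radius
    return np.column_stack(
        [center[0] + a * np.cos(theta), center[1] + b * np.sin(theta)]
    )


def random_star_polygon(rng, center, max_radius, n_vertices=12) -> np.ndarray:
    """Simple (star-shaped, generally non-convex) polygon."""
    theta = np.sort(rng.uniform(0, 2 * math.pi, size=n_vertices))
    r = rng.uniform(0.3, 1.0, size=n_vertices) * max_radius
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )
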