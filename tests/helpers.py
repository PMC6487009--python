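"""Independent brute-force oracles used across the test modules."""

import itertools

import numpy as np


def point_in_polygon(r, c, verts):
    """Even-odd ray casting with an explicit on-edge check (edge = inside).

    Deliberately scalar and loop-based; shares no code with the package's
    vectorized point-in-polygon path.
    """
    n = len(verts)
    inside = False
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        # on-segment check
        cross = (c2 - c1) * (r - r1) - (r2 - r1) * (c - c1)
        if abs(cross) < 1e-12:
            if min(r1, r2) - 1e-12 <= r <= max(r1, r2) + 1e-12 and (
                min(c1, c2) - 1e-12 <= c <= max(c1, c2) + 1e-12
            ):
                return True
        # horizontal-ray crossing test in the row direction
        if (r1 > r) != (r2 > r):
            c_cross = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
            if c < c_cross:
                inside = not inside
    return inside


def brute_force_mask(shape, verts):
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            mask[r, c] = point_in_polygon(float(r), float(c), verts)
    return mask


def star_polygon(rng, center, n_vertices, r_min, r_max):
    """Random star-shaped (hence simple) polygon, (row, col) vertices."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_min, r_max, n_vertices)
    cy, cx = center
    return [
        (cy + rad * np.sin(a), cx + rad * np.cos(a))
        for a, rad in zip(angles, radii)
    ]


def exact_mwu_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for a in xs for b in ys if a > b)
        u += 0.5 * sum(1 for a in xs for b in ys if a == b)
        return u

    observed = u_stat(tuple(range(n1)))
    n2 = len(y)
    mean_u = n1 * n2 / 2.0
    obs_dev = abs(observed - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mean_u) >= obs_dev - 1e-12:
            count += 1
    return count / total


def pair_count_auc(scores, labels):
    """O(n^2) concordant-pair AUC with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = len(pos) * len(neg)
    conc = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return conc / total
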