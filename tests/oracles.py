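"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a quantity by the most literal route available —
explicit 3x3 rotation matrices, all-pairs distance loops, exhaustive pixel
sums — so that agreement with the package is a meaningful cross-check rather
than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def rotation_x(alpha: float) -> np.ndarray:
    c, s = math.cos(alpha), math.sin(alpha)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_z(psi: float) -> np.ndarray:
    c, s = math.cos(psi), math.sin(psi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def spamm_mz_matrix_oracle(psi: float, total_flip_deg: float, weights) -> float:
    """Final Mz of the SPAMM train by explicit rotation-matrix composition."""
    weights = np.asarray(weights, dtype=float)
    flips = math.radians(total_flip_deg) * weights / weights.sum()
    m = np.array([0.0, 0.0, 1.0])
    for i, alpha in enumerate(flips):
        if i > 0:
            m = rotation_z(psi) @ m
        m = rotation_x(alpha) @ m
    return float(m[2])


def signed_distance_oracle(mask: np.ndarray) -> np.ndarray:
    """Signed normalized distance map via an all-pairs pixel-centre loop."""
    mask = np.asarray(mask) > 0
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    raw = np.zeros(mask.shape, dtype=float)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            here = np.array([r, c])
            if mask[r, c]:
                raw[r, c] = math.sqrt(((bg - here) ** 2).sum(axis=1).min())
            else:
                raw[r, c] = -math.sqrt(((fg - here) ** 2).sum(axis=1).min())
    return raw / np.abs(raw).max()


def dice_oracle(g: np.ndarray, p: np.ndarray) -> float:
    """Dice via explicit coordinate-set arithmetic."""
    gs = {tuple(x) for x in np.argwhere(np.asarray(g) > 0)}
    ps = {tuple(x) for x in np.argwhere(np.asarray(p) > 0)}
    if not gs and not ps:
        return 1.0
    return 2.0 * len(gs & ps) / (len(gs) + len(ps))


def contour_oracle(mask: np.ndarray) -> set[tuple[int, int]]:
    """Boundary pixels by per-pixel 4-neighbour inspection."""
    mask = np.asarray(mask) > 0
    rows, cols = mask.shape
    out = set()
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or not mask[rr, cc]:
                    out.add((r, c))
                    break
    return out


def hausdorff_oracle(g: np.ndarray, p: np.ndarray, spacing=(1.0, 1.0), q: float = 0.95) -> float:
    """Symmetric q-percentile Hausdorff via brute-force nearest neighbours."""
    cg = [(r * spacing[0], c * spacing[1]) for r, c in sorted(contour_oracle(g))]
    cp = [(r * spacing[0], c * spacing[1]) for r, c in sorted(contour_oracle(p))]

    def directed(xs, ys):
        nearest = [min(math.dist(x, y) for y in ys) for x in xs]
        return float(np.quantile(nearest, q))

    return max(directed(cg, cp), directed(cp, cg))


def shape_loss_oracle(g: np.ndarray, p: np.ndarray, k: float) -> float:
    """Boundary-aware loss by explicit per-channel, per-pixel summation."""
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    if g.ndim == 2:
        g, p = g[None], p[None]
    total = 0.0
    for gc, pc in zip(g, p):
        phi = signed_distance_oracle(gc)
        si = np.where(phi >= 0, 1.0 / (1.0 + np.exp(-(1.0 - phi) / k)), 0.0)
        acc = 0.0
        for r in range(gc.shape[0]):
            for c in range(gc.shape[1]):
                acc += abs(pc[r, c] - si[r, c])
        total += acc / gc.sum()
    return total / g.shape[0]


def cross_entropy_oracle(g: np.ndarray, p: np.ndarray, eps: float) -> float:
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    if g.ndim == 2:
        g, p = g[None], p[None]
    total = 0.0
    for gc, pc in zip(g, p):
        for r in range(gc.shape[0]):
            for c in range(gc.shape[1]):
                total += -gc[r, c] * math.log(max(pc[r, c], eps))
    return total / g.shape[0]


def random_mask_with_both_phases(rng: np.random.Generator, shape, p_fg: float = 0.4) -> np.ndarray:
    """Random binary mask guaranteed to contain foreground and background."""
    while True:
        m = (rng.random(shape) < p_fg).astype(np.uint8)
        if 0 < m.sum() < m.size:
            return m
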