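"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the ellipsoid area oracle
is a numerical surface integral, the Ward oracle an exhaustive greedy search
over the within-cluster sum-of-squares objective, and the distance oracle a
brute-force minimum over all voxel pairs.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import simpson


def ellipsoid_area_quadrature(a: float, b: float, c: float, n: int = 600) -> float:
    """Surface integral of an ellipsoid via the parametric cross-product norm."""
    theta = np.linspace(0.0, 2.0 * np.pi, n)
    phi = np.linspace(0.0, np.pi, n)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    sin_p, cos_p = np.sin(P), np.cos(P)
    sin_t, cos_t = np.sin(T), np.cos(T)
    # |r_phi × r_theta| for x=a sinφ cosθ, y=b sinφ sinθ, z=c cosφ
    integrand = sin_p * np.sqrt(
        (b * c * sin_p * cos_t) ** 2
        + (a * c * sin_p * sin_t) ** 2
        + (a * b * cos_p) ** 2
    )
    return float(simpson(simpson(integrand, x=phi, axis=1), x=theta))


def ward_linkage_bruteforce(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Greedy agglomeration minimizing the within-cluster SS increase.

    At each step, merge the pair of clusters (A, B) minimizing
    ΔSS = |A||B|/(|A|+|B|) · ||mean(A) − mean(B)||², recording the merge as
    (members_A, members_B, height) with height = sqrt(2·ΔSS) so that two
    singletons merge at their Euclidean distance.
    """
    X = np.asarray(X, dtype=float)
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                A, B = clusters[i], clusters[j]
                mu_a = X[list(A)].mean(axis=0)
                mu_b = X[list(B)].mean(axis=0)
                delta = (len(A) * len(B) / (len(A) + len(B))) * float(
                    np.sum((mu_a - mu_b) ** 2)
                )
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        delta, i, j = best
        A, B = clusters[i], clusters[j]
        merges.append((A, B, float(np.sqrt(2.0 * delta))))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(A | B)
    return merges


def linkage_matrix_to_merges(Z: np.ndarray, n: int) -> list[tuple[frozenset, frozenset, float]]:
    """Convert a scipy-style linkage matrix into (members, members, height) merges."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (left, right, height, _) in enumerate(np.asarray(Z)):
        A, B = members[int(left)], members[int(right)]
        merges.append((A, B, float(height)))
        members[n + row_idx] = A | B
    return merges


def min_surface_distance_bruteforce(cell_voxels: np.ndarray,
                                    surface_voxels: np.ndarray,
                                    spacing) -> float:
    """Minimum Euclidean distance over all (cell voxel, surface voxel) pairs."""
    spacing = np.asarray(spacing, dtype=float)
    a = cell_voxels * spacing
    b = surface_voxels * spacing
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())
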