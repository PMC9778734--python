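"""Independent brute-force oracles, deliberately written with naive loops so
they share no code path with the implementations they check."""

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

KB = 0.0019872041


def wham_fixed_point_oracle(samples_per_window, centers, force_constants, edges,
                            temperature, n_iter=200000, tol=1e-14):
    """Naive WHAM fixed-point iteration over explicit Python loops.

    Returns (F per window, normalized density per bin).
    """
    beta = 1.0 / (KB * temperature)
    n_win = len(samples_per_window)
    n_bin = len(edges) - 1
    mids = [(edges[k] + edges[k + 1]) / 2.0 for k in range(n_bin)]

    hist = [[0] * n_bin for _ in range(n_win)]
    for j, xs in enumerate(samples_per_window):
        for x in xs:
            for k in range(n_bin):
                # right-open bins, last bin closed, as numpy.histogram does
                if edges[k] <= x < edges[k + 1] or (k == n_bin - 1 and x == edges[-1]):
                    hist[j][k] += 1
                    break
    n_j = [sum(row) for row in hist]
    total = [sum(hist[j][k] for j in range(n_win)) for k in range(n_bin)]

    def bias(j, k):
        return 0.5 * force_constants[j] * (mids[k] - centers[j]) ** 2

    f = [0.0] * n_win
    for _ in range(n_iter):
        p = []
        for k in range(n_bin):
            denom = sum(n_j[j] * math.exp(-beta * (bias(j, k) - f[j])) for j in range(n_win))
            p.append(total[k] / denom if total[k] > 0 else 0.0)
        s = sum(p)
        p = [v / s for v in p]
        f_new = []
        for j in range(n_win):
            z = sum(p[k] * math.exp(-beta * bias(j, k)) for k in range(n_bin))
            f_new.append(-math.log(z) / beta)
        f_new = [v - f_new[0] for v in f_new]
        delta = max(abs(a - b) for a, b in zip(f, f_new))
        f = f_new
        if delta < tol:
            break
    return np.array(f), np.array(p)


def gromos_oracle(coords, cutoff, rmsd_func):
    """O(n²) reference of greedy neighbor-counting clustering.

    ``rmsd_func(a, b)`` supplies the (possibly fitted) pairwise RMSd.
    Returns (assignments, centroids).
    """
    n = len(coords)
    dist = [[rmsd_func(coords[i], coords[j]) for j in range(n)] for i in range(n)]
    assignments = [-1] * n
    centroids = []
    remaining = set(range(n))
    cluster = 0
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if dist[i][j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in sorted(remaining) if dist[best][j] <= cutoff]
        for j in members:
            assignments[j] = cluster
            remaining.discard(j)
        centroids.append(best)
        cluster += 1
    return assignments, centroids


def superpose_grid_oracle(mobile, reference, coarse=18):
    """Minimal RMSd over rigid rotations via Euler-angle grid + simplex refinement."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def rmsd_of(angles):
        rot = Rotation.from_euler("zyx", angles)
        diff = rot.apply(mobile) - reference
        return float(np.sqrt((diff ** 2).sum() / len(mobile)))

    grid = np.linspace(-np.pi, np.pi, coarse, endpoint=False)
    best_angles, best = None, np.inf
    for a in grid:
        for b in grid[: coarse // 2]:
            for c in grid:
                v = rmsd_of((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


def nearest_vertex_oracle(phi, theta, table):
    """Brute-force scan for the nearest canonical vertex by chord distance."""

    def unit(p, t):
        p, t = math.radians(p), math.radians(t)
        return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])

    target = unit(phi, theta)
    best_label, best_d = None, np.inf
    for label in sorted(table):
        d = float(np.linalg.norm(unit(*table[label]) - target))
        if d < best_d - 1e-12:
            best_label, best_d = label, d
    return best_label


def boltzmann_density(potential, grid, temperature):
    """Normalized stationary density on a grid by direct quadrature."""
    beta = 1.0 / (KB * temperature)
    dens = np.exp(-beta * potential.energy(grid))
    return dens / np.trapezoid(dens, grid)
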