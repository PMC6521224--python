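"""Independent brute-force oracle for the WMH region-growing segmentation.

Pure Python (sets, BFS, explicit loops), sharing no code with the package
implementation.  Intended for exhaustive comparison on small grids with
integer intensities, where floating-point sums are exact and the two
routes must agree voxel for voxel.
"""

from __future__ import annotations

import itertools
import math

NEIGHBORS = {
    6: [d for d in itertools.product((-1, 0, 1), repeat=3) if sum(map(abs, d)) == 1],
    18: [d for d in itertools.product((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, d)) <= 2],
    26: [d for d in itertools.product((-1, 0, 1), repeat=3) if any(d)],
}


def _neighbors(vox, shape, conn):
    for d in NEIGHBORS[conn]:
        w = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
        if 0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]:
            yield w


def wm_stats(intensity, labels, shape):
    vals = [intensity[v] for v in itertools.product(*map(range, shape)) if labels[v] == 1]
    n = len(vals)
    if n < 2:
        raise ValueError("need >= 2 WM voxels")
    mu = sum(vals) / n
    var = sum((x - mu) ** 2 for x in vals) / (n - 1)
    sigma = math.sqrt(var)
    if sigma == 0:
        raise ValueError("zero WM SD")
    return mu, sigma


def connected_components(voxels, shape, conn):
    voxels = set(voxels)
    comps = []
    while voxels:
        start = voxels.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in _neighbors(v, shape, conn):
                if w in voxels:
                    voxels.remove(w)
                    comp.add(w)
                    frontier.append(w)
        comps.append(frozenset(comp))
    return comps


def detect_seeds(intensity, labels, shape, mu, sigma, z_seed=2.5, min_size=3,
                 conn=26, allowed=(1, 2)):
    thr = mu + z_seed * sigma
    supra = [v for v in itertools.product(*map(range, shape))
             if labels[v] in allowed and intensity[v] >= thr]
    comps = [c for c in connected_components(supra, shape, conn) if len(c) >= min_size]
    comps.sort(key=lambda c: (-max(intensity[v] for v in c), min(c)))
    return comps


def grow(intensity, labels, shape, seed, mu, sigma, growth_fraction=0.95,
         z_stop=2.0, conn=26, allowed=(1, 2)):
    cluster = set(seed)
    stop = mu + z_stop * sigma
    while True:
        mean = sum(intensity[v] for v in cluster) / len(cluster)
        batch = set()
        for v in cluster:
            for w in _neighbors(v, shape, conn):
                if w not in cluster and labels[w] in allowed \
                        and intensity[w] >= growth_fraction * mean:
                    batch.add(w)
        if not batch:
            break
        trial = cluster | batch
        if sum(intensity[v] for v in trial) / len(trial) < stop:
            break  # rollback
        cluster = trial
    return frozenset(cluster)


def segment(intensity, labels, shape, z_seed=2.5, min_size=3, growth_fraction=0.95,
            z_stop=2.0, conn=26, allowed=(1, 2)):
    """Full pipeline; returns a list of (frozenset, class) in final order."""
    mu, sigma = wm_stats(intensity, labels, shape)
    seeds = detect_seeds(intensity, labels, shape, mu, sigma, z_seed, min_size, conn, allowed)
    clusters = [grow(intensity, labels, shape, s, mu, sigma, growth_fraction,
                     z_stop, conn, allowed) for s in seeds]

    def touching(a, b):
        for v in a:
            if v in b:
                return True
            for w in _neighbors(v, shape, conn):
                if w in b:
                    return True
        return False

    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if touching(clusters[i], clusters[j]):
                    union = set(clusters[i]) | set(clusters[j])
                    clusters[i] = grow(intensity, labels, shape, union, mu, sigma,
                                       growth_fraction, z_stop, conn, allowed)
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break

    out = []
    for c in clusters:
        pv = False
        for v in c:
            for w in _neighbors(v, shape, conn):
                if labels[w] == 4:
                    pv = True
                    break
            if pv:
                break
        out.append((c, "periventricular" if pv else "deep"))
    return out
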