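"""Independent reference implementations used only to check the package.

Everything here is deliberately brute-force and shares no code with the
implementation under test: exhaustive threshold search, iterative grayscale
reconstruction, a heap-based priority flood, closed-form test statistics.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy import ndimage as ndi


def brute_force_otsu(values, nbins: int = 256) -> float:
    """Exhaustively minimize the within-class variance over all histogram
    split points; returns the threshold (upper edge of the low class)."""
    x = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(x, bins=nbins, range=(x.min(), x.max()))
    mids = 0.5 * (edges[:-1] + edges[1:])
    best, best_k = np.inf, None
    for k in range(nbins - 1):
        c0, c1 = counts[: k + 1], counts[k + 1:]
        n0, n1 = c0.sum(), c1.sum()
        within = 0.0
        if n0 > 0:
            m0 = (c0 * mids[: k + 1]).sum() / n0
            within += (c0 * (mids[: k + 1] - m0) ** 2).sum()
        if n1 > 0:
            m1 = (c1 * mids[k + 1:]).sum() / n1
            within += (c1 * (mids[k + 1:] - m1) ** 2).sum()
        if within < best - 1e-12:
            best, best_k = within, k
    return float(edges[best_k + 1])


def binned_within_variance(values, threshold, nbins: int = 256) -> float:
    """Within-class variance of the split ``values > threshold`` on the same
    256-bin histogram convention (class statistics from bin midpoints)."""
    x = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(x, bins=nbins, range=(x.min(), x.max()))
    mids = 0.5 * (edges[:-1] + edges[1:])
    lo = mids <= threshold
    within = 0.0
    for cls in (lo, ~lo):
        n = counts[cls].sum()
        if n > 0:
            m = (counts[cls] * mids[cls]).sum() / n
            within += (counts[cls] * (mids[cls] - m) ** 2).sum()
    return float(within)


def welch_closed_form(a, b):
    """Hand evaluation of Welch's t, Welch–Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return float(t), float(df), float(p)


def quantile_linear(values, q):
    """Linear-interpolation quantile from first principles (sorted order
    statistics, position q·(n−1))."""
    v = np.sort(np.asarray(values, float))
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


# ---------------------------------------------------------------------------
# watershed reference: reconstruction-based h-minima + heap priority flood
# ---------------------------------------------------------------------------

def _struct(conn_rank):
    return ndi.generate_binary_structure(3, conn_rank)


def hminima_reference(landscape, h, conn_rank=3):
    """Grayscale reconstruction by erosion of (landscape + h) over landscape,
    iterated to the fixed point."""
    rec = landscape + h
    footprint = _struct(conn_rank)
    while True:
        eroded = ndi.grey_erosion(rec, footprint=footprint, mode="nearest")
        nxt = np.maximum(landscape, eroded)
        if np.array_equal(nxt, rec):
            return rec
        rec = nxt


def regional_minima_reference(landscape, conn_rank=3):
    """Boolean regional minima (plateau-aware) by flood filling plateaus and
    checking for lower neighbors."""
    fp = _struct(conn_rank)
    fp_ring = fp.copy()
    fp_ring[1, 1, 1] = False
    neigh_min = ndi.minimum_filter(landscape, footprint=fp_ring, mode="nearest")
    candidate = landscape <= neigh_min  # no strictly lower neighbor
    # adjacent candidates necessarily share one value, so connected groups
    # of candidates are (sub-)plateaus; a group is a regional minimum only
    # if every surrounding voxel is strictly higher (an equal-valued ring
    # voxel means the plateau continues toward an escape)
    plateau, n = ndi.label(candidate, structure=fp)
    out = np.zeros_like(candidate)
    for lbl in range(1, n + 1):
        region = plateau == lbl
        dil = ndi.binary_dilation(region, structure=fp)
        ring = dil & ~region
        if not ring.any() or (landscape[ring] > landscape[region].max()).all():
            out |= region
    return out


def priority_flood_reference(landscape, markers, conn_rank=3):
    """Exhaustive heap-based watershed flood from integer markers.

    Voxels are popped in increasing landscape value; ties broken by
    insertion order then lexicographic (z, y, x).
    """
    shape = landscape.shape
    labels = markers.copy()
    heap = []
    counter = 0
    offsets = np.argwhere(_struct(conn_rank)) - 1
    offsets = [tuple(o) for o in offsets if any(o)]
    for idx in np.argwhere(markers > 0):
        z, y, x = map(int, idx)
        heapq.heappush(heap, (landscape[z, y, x], counter, z, y, x))
        counter += 1
    while heap:
        _, _, z, y, x = heapq.heappop(heap)
        lbl = labels[z, y, x]
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if labels[nz, ny, nx] == 0:
                    labels[nz, ny, nx] = lbl
                    heapq.heappush(
                        heap, (landscape[nz, ny, nx], counter, nz, ny, nx))
                    counter += 1
    return labels


def watershed_reference(indicator_data, h, conn_rank=3):
    """Full reference segmentation: negate, h-minima, minima markers, flood."""
    landscape = -indicator_data
    suppressed = hminima_reference(landscape, h, conn_rank)
    minima = regional_minima_reference(suppressed, conn_rank)
    markers, _ = ndi.label(minima, structure=_struct(3))
    return priority_flood_reference(suppressed, markers, conn_rank)


def partitions_equal(a, b) -> bool:
    """True if two label images define the same partition (up to label
    permutation)."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(set(a.tolist())) == len(set(b.tolist()))
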