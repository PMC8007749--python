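"""Independent brute-force oracles for the connectomics statistics.

Everything here is written as naive, loop-based recomputation from the
definitions, deliberately sharing no code with the package implementations
it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def brute_resample(points: np.ndarray, step: float) -> np.ndarray:
    """Arc-length resampling by explicit marching (reference implementation)."""
    pts = np.asarray(points, dtype=float)
    seg = [0.0]
    for a, b in zip(pts[:-1], pts[1:]):
        seg.append(seg[-1] + math.dist(a, b))
    total = seg[-1]
    stations = [i * step for i in range(int(total // step) + 1)]
    if stations[-1] < total:
        stations.append(total)
    out = []
    for s in stations:
        j = 0
        while j + 1 < len(seg) - 1 and seg[j + 1] < s:
            j += 1
        span = seg[j + 1] - seg[j]
        t = 0.0 if span == 0 else (s - seg[j]) / span
        out.append(pts[j] + t * (pts[j + 1] - pts[j]))
    return np.asarray(out)


def brute_voxel_of(point, origin, voxel_size):
    return tuple(int(math.floor((point[d] - origin[d]) / voxel_size))
                 for d in range(3))


def brute_field(point, centres, amplitude, ke=1.0, core=1.0):
    total = 0.0
    for c in np.atleast_2d(centres):
        r = math.dist(point, c)
        total += ke * amplitude / max(r, core) ** 2
    return total


def brute_recruit(streamlines, field_values, grid_origin, voxel_size, grid_shape,
                  vat_mask, step=0.5):
    """Per-streamline weights: max nearest-voxel field over in-VAT samples,
    normalised by the global in-VAT maximum."""
    per_max = []
    for sl in streamlines:
        best = -1.0
        for p in brute_resample(sl, step):
            idx = brute_voxel_of(p, grid_origin, voxel_size)
            if all(0 <= idx[d] < grid_shape[d] for d in range(3)) and vat_mask[idx]:
                best = max(best, field_values[idx])
        per_max.append(best)
    gmax = max(per_max)
    if gmax <= 0:
        return np.zeros(len(streamlines))
    return np.array([max(m, 0.0) / gmax for m in per_max])


def brute_profile(streamlines, weights, grid_origin, voxel_size, grid_shape,
                  step=0.5):
    """Voxel walk: each streamline adds its weight once per distinct voxel."""
    vol = np.zeros(grid_shape)
    for sl, w in zip(streamlines, weights):
        if w <= 0:
            continue
        seen = set()
        for p in brute_resample(sl, step):
            idx = brute_voxel_of(p, grid_origin, voxel_size)
            if all(0 <= idx[d] < grid_shape[d] for d in range(3)):
                seen.add(idx)
        for idx in seen:
            vol[idx] += w
    return vol


def brute_rmap(profiles, improvement, min_nonzero=3):
    """Voxel-by-voxel scipy.stats.spearmanr with the validity rule."""
    P = np.stack([p.reshape(-1) for p in profiles])
    out = np.full(P.shape[1], np.nan)
    for v in range(P.shape[1]):
        col = P[:, v]
        if (col > 0).sum() < min_nonzero or np.ptp(col) == 0:
            continue
        out[v] = stats.spearmanr(col, improvement)[0]
    return out


def brute_spatial_similarity(profile, rho, cap=1.0 - 1e-7):
    mask = np.isfinite(rho)
    x, y = profile.reshape(-1)[mask], rho[mask]
    r = stats.pearsonr(x, y)[0]
    return math.atanh(max(-cap, min(cap, r)))


def brute_fibre_t(connected_col, improvement, min_group=2):
    """scipy two-sample Student t for one fibre; None when unscorable."""
    a = improvement[connected_col]
    b = improvement[~connected_col]
    if len(a) < min_group or len(b) < min_group:
        return None
    return stats.ttest_ind(a, b, equal_var=True)


def pooled_t(a, b):
    """Closed-form pooled two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def paired_t_power(mean, sd, n, alpha=0.05):
    """Exact power of a two-sided paired t-test (noncentral t)."""
    df = n - 1
    nc = mean / (sd / math.sqrt(n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return (1 - stats.nct.cdf(tcrit, df, nc)) + stats.nct.cdf(-tcrit, df, nc)
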