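"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain per-pixel / per-pair Python loops,
deliberately sharing no code with the package's vectorised engine, so
that agreement between the two is a meaningful check of both matrix
construction and feature formulas.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def oracle_discretize_fbw(image, mask, width):
    vals = [image[r, c] for r, c in zip(*np.nonzero(mask))]
    lo = min(vals)
    out = np.zeros_like(np.asarray(image), dtype=int)
    for r, c in zip(*np.nonzero(mask)):
        out[r, c] = int(math.floor((image[r, c] - lo) / width)) + 1
    return out


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def oracle_first_order(values, levels_in_mask):
    """Direct formulas on a flat list of in-mask values."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    counts = {}
    for lv in levels_in_mask:
        counts[lv] = counts.get(lv, 0) + 1
    probs = [c / n for c in counts.values()]
    p10, p25, p75, p90 = (np.percentile(x, q) for q in (10, 25, 75, 90))
    band = [v for v in x if p10 <= v <= p90]
    bmean = sum(band) / len(band)
    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Variance": m2,
        "Skewness": m3 / m2 ** 1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2 ** 2 if m2 > 0 else 0.0,
        "Energy": sum(v * v for v in x),
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": x[0],
        "Maximum": x[-1],
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation":
            sum(abs(v - bmean) for v in band) / len(band),
        "RootMeanSquared": math.sqrt(sum(v * v for v in x) / n),
        "Uniformity": sum(p * p for p in probs),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(p75 - p25),
        "RobustRange": float(p90 - p10),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm_matrix(levels, mask, angle, distance=1):
    """Symmetric normalised co-occurrence matrix by pair enumeration."""
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    vals = sorted({int(levels[r, c]) for r, c in zip(*np.nonzero(mask))})
    idx = {v: i for i, v in enumerate(vals)}
    m = np.zeros((len(vals), len(vals)))
    h, w = np.asarray(levels).shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if mask[r, c] and 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                a, b = idx[int(levels[r, c])], idx[int(levels[r2, c2])]
                m[a, b] += 1
                m[b, a] += 1  # symmetric
    if m.sum() > 0:
        m = m / m.sum()
    return m, vals


def oracle_glcm_features(p, vals):
    ng = len(vals)
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum(px[i] * vals[i] for i in range(ng))
    sigma2 = sum(px[i] * (vals[i] - mu) ** 2 for i in range(ng))

    def plog(v):
        return v * math.log2(v) if v > 0 else 0.0

    psum, pdiff = {}, {}
    for i in range(ng):
        for j in range(ng):
            psum[vals[i] + vals[j]] = psum.get(vals[i] + vals[j], 0) + p[i][j]
            d = abs(vals[i] - vals[j])
            pdiff[d] = pdiff.get(d, 0) + p[i][j]
    da = sum(k * v for k, v in pdiff.items())
    hx = -sum(plog(v) for v in px)
    hxy = -sum(plog(p[i][j]) for i in range(ng) for j in range(ng))
    hxy1 = -sum(p[i][j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng)
                if p[i][j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(plog(px[i] * px[j]) for i in range(ng) for j in range(ng))

    q = [[sum(p[i][k] * p[j][k] / (px[i] * px[k])
              for k in range(ng) if px[i] > 0 and px[k] > 0)
          for j in range(ng)] for i in range(ng)]
    eig = sorted(np.real(np.linalg.eigvals(np.array(q))))
    mcc = math.sqrt(max(0.0, eig[-2])) if ng > 1 else 1.0

    feats = {
        "Autocorrelation": sum(p[i][j] * vals[i] * vals[j]
                               for i in range(ng) for j in range(ng)),
        "JointAverage": mu,
        "ClusterProminence": sum(p[i][j] * (vals[i] + vals[j] - 2 * mu) ** 4
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum(p[i][j] * (vals[i] + vals[j] - 2 * mu) ** 3
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum(p[i][j] * (vals[i] + vals[j] - 2 * mu) ** 2
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum(p[i][j] * (vals[i] - vals[j]) ** 2
                        for i in range(ng) for j in range(ng)),
        "Correlation": 1.0 if sigma2 <= 0 else
            (sum(p[i][j] * vals[i] * vals[j]
                 for i in range(ng) for j in range(ng)) - mu * mu) / sigma2,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(plog(v) for v in pdiff.values()),
        "DifferenceVariance": sum(v * (k - da) ** 2
                                  for k, v in pdiff.items()),
        "JointEnergy": sum(p[i][j] ** 2
                           for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "Imc1": 0.0 if hx == 0 else (hxy - hxy1) / hx,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2 * (hxy2 - hxy)))),
        "Idm": sum(p[i][j] / (1 + (vals[i] - vals[j]) ** 2)
                   for i in range(ng) for j in range(ng)),
        "Idmn": sum(p[i][j] / (1 + ((vals[i] - vals[j]) / ng) ** 2)
                    for i in range(ng) for j in range(ng)),
        "Id": sum(p[i][j] / (1 + abs(vals[i] - vals[j]))
                  for i in range(ng) for j in range(ng)),
        "Idn": sum(p[i][j] / (1 + abs(vals[i] - vals[j]) / ng)
                   for i in range(ng) for j in range(ng)),
        "InverseVariance": sum(p[i][j] / (vals[i] - vals[j]) ** 2
                               for i in range(ng) for j in range(ng)
                               if i != j),
        "MaximumProbability": max(p[i][j]
                                  for i in range(ng) for j in range(ng)),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": -sum(plog(v) for v in psum.values()),
        "SumSquares": sum(p[i][j] * (vals[i] - mu) ** 2
                          for i in range(ng) for j in range(ng)),
        "Mcc": mcc,
    }
    return feats


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def oracle_glrlm_runs(levels, mask, angle):
    """All (level, run length) runs along a direction by explicit scan."""
    h, w = np.asarray(levels).shape
    dr, dc = OFFSETS[angle]
    # starting points: cells with no valid predecessor
    runs = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w:
                if mask[pr, pc] and mask[r, c] and \
                        levels[pr, pc] == levels[r, c]:
                    continue  # not a run start
            if not mask[r, c]:
                continue
            # walk forward
            length = 1
            rr, cc = r + dr, c + dc
            while 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                    and levels[rr, cc] == levels[r, c]:
                length += 1
                rr, cc = rr + dr, cc + dc
            runs.append((int(levels[r, c]), length))
    return runs


KEYS16 = ("small", "large", "gln", "glnn", "jn", "jnn", "pct", "glv", "jv",
          "ent", "lgl", "hgl", "sl", "sh", "ll", "lh")
# GLDM reports neither a normalised GLN nor a percentage (every pixel
# contributes exactly one dependence entry)
KEYS_GLDM = ("small", "large", "gln", "jn", "jnn", "glv", "jv", "ent",
             "lgl", "hgl", "sl", "sh", "ll", "lh")


def srzm_style_features(counts, i_vals, j_vals, n_pixels, names, keys=KEYS16):
    """Shared run/zone/dependence formula block, looped."""
    ns = sum(counts[i][j] for i in range(len(i_vals))
             for j in range(len(j_vals)))
    p = [[counts[i][j] / ns for j in range(len(j_vals))]
         for i in range(len(i_vals))]
    mu_i = sum(p[i][j] * i_vals[i] for i in range(len(i_vals))
               for j in range(len(j_vals)))
    mu_j = sum(p[i][j] * j_vals[j] for i in range(len(i_vals))
               for j in range(len(j_vals)))
    si = [sum(counts[i][j] for j in range(len(j_vals)))
          for i in range(len(i_vals))]
    sj = [sum(counts[i][j] for i in range(len(i_vals)))
          for j in range(len(j_vals))]

    def s(fn):
        return sum(fn(i, j) * counts[i][j] for i in range(len(i_vals))
                   for j in range(len(j_vals))) / ns

    vals = {
        "small": s(lambda i, j: 1.0 / j_vals[j] ** 2),
        "large": s(lambda i, j: j_vals[j] ** 2),
        "gln": sum(v ** 2 for v in si) / ns,
        "glnn": sum(v ** 2 for v in si) / ns ** 2,
        "jn": sum(v ** 2 for v in sj) / ns,
        "jnn": sum(v ** 2 for v in sj) / ns ** 2,
        "pct": ns / n_pixels,
        "glv": sum(p[i][j] * (i_vals[i] - mu_i) ** 2
                   for i in range(len(i_vals)) for j in range(len(j_vals))),
        "jv": sum(p[i][j] * (j_vals[j] - mu_j) ** 2
                  for i in range(len(i_vals)) for j in range(len(j_vals))),
        "ent": -sum(p[i][j] * math.log2(p[i][j])
                    for i in range(len(i_vals)) for j in range(len(j_vals))
                    if p[i][j] > 0),
        "lgl": s(lambda i, j: 1.0 / i_vals[i] ** 2),
        "hgl": s(lambda i, j: i_vals[i] ** 2),
        "sl": s(lambda i, j: 1.0 / (i_vals[i] ** 2 * j_vals[j] ** 2)),
        "sh": s(lambda i, j: i_vals[i] ** 2 / j_vals[j] ** 2),
        "ll": s(lambda i, j: j_vals[j] ** 2 / i_vals[i] ** 2),
        "lh": s(lambda i, j: i_vals[i] ** 2 * j_vals[j] ** 2),
    }
    return dict(zip(names, [vals[k] for k in keys]))


def oracle_glrlm_features(levels, mask, angle, names):
    runs = oracle_glrlm_runs(levels, mask, angle)
    i_vals = sorted({lv for lv, _ in runs})
    max_len = max(ln for _, ln in runs)
    j_vals = list(range(1, max_len + 1))
    counts = [[0.0] * max_len for _ in i_vals]
    for lv, ln in runs:
        counts[i_vals.index(lv)][ln - 1] += 1
    return counts, srzm_style_features(counts, i_vals, j_vals,
                                       int(np.sum(mask)), names)


# ---------------------------------------------------------------------------
# GLSZM (flood fill) and GLDM (neighbour loop)
# ---------------------------------------------------------------------------

def oracle_glszm_zones(levels, mask):
    h, w = np.asarray(levels).shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                level = int(levels[r, c])
                stack, size = [(r, c)], 0
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and \
                                    mask[nr, nc] and not seen[nr, nc] and \
                                    int(levels[nr, nc]) == level:
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                zones.append((level, size))
    return zones


def oracle_gldm_entries(levels, mask, alpha=0):
    h, w = np.asarray(levels).shape
    entries = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and \
                            abs(int(levels[nr, nc]) - int(levels[r, c])) <= alpha:
                        dep += 1
            entries.append((int(levels[r, c]), dep))
    return entries


def zones_to_features(entries, n_pixels, names, keys=KEYS16):
    """Turn (level, size) pairs into a matrix and the 16/14 features."""
    i_vals = sorted({lv for lv, _ in entries})
    max_j = max(j for _, j in entries)
    j_vals = list(range(1, max_j + 1))
    counts = [[0.0] * max_j for _ in i_vals]
    for lv, j in entries:
        counts[i_vals.index(lv)][j - 1] += 1
    return counts, srzm_style_features(counts, i_vals, j_vals,
                                       n_pixels, names, keys)
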