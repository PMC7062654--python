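"""Independent literal-formula implementations used as oracles.

Everything here is written as plain loops straight from the defining
formulas, deliberately ignoring vectorization, so that agreement with the
package implementation is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

DIR_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-pixel evaluation of the mu +/- 3 sigma quantization formula."""
    mu = sum(values) / len(values)
    sigma = math.sqrt(sum((v - mu) ** 2 for v in values) / len(values))
    if sigma == 0:
        return np.ones(len(values), dtype=int)
    lower, upper = mu - 3 * sigma, mu + 3 * sigma
    out = []
    for v in values:
        x = min(max(v, lower), upper)
        lv = 1 + math.floor((x - lower) / (upper - lower) * n_levels)
        out.append(min(lv, n_levels))
    return np.array(out)


def oracle_his(levels: np.ndarray) -> dict:
    lv = [float(v) for v in levels]
    n = len(lv)
    mean = sum(lv) / n
    var = sum((v - mean) ** 2 for v in lv) / n
    if var == 0:
        skew = kurt = math.nan
    else:
        sd = math.sqrt(var)
        skew = sum((v - mean) ** 3 for v in lv) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in lv) / n / sd**4 - 3.0
    p = np.percentile(lv, [1, 10, 50, 90, 99])
    return {
        "mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt,
        "perc01": p[0], "perc10": p[1], "perc50": p[2], "perc90": p[3], "perc99": p[4],
    }


def oracle_glcm(level_img: np.ndarray, mask: np.ndarray, d: int, angle: int, n_levels: int):
    """Enumerate every ordered in-mask pixel pair at the offset, symmetrized."""
    dr, dc = DIR_OFFSETS[angle]
    dr, dc = dr * d, dc * d
    nr, nc = mask.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(nr):
        for c in range(nc):
            for sr, sc in ((dr, dc), (-dr, -dc)):
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < nr and 0 <= c2 < nc and mask[r, c] and mask[r2, c2]:
                    counts[level_img[r, c] - 1, level_img[r2, c2] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else None


def oracle_glcm_features(P: np.ndarray) -> dict:
    ng = P.shape[0]

    def ln(x):
        return math.log(x) if x > 0 else 0.0

    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    asm = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    if var > 0:
        corr = (
            sum((i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng)) - mu**2
        ) / var
    else:
        corr = math.nan
    sos = sum((i + 1 - mu) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i, j]
    sa = sum(k * v for k, v in p_sum.items())
    sv = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    se = -sum(v * ln(v) for v in p_sum.values())
    dm = sum(k * v for k, v in p_diff.items())
    dv = sum((k - dm) ** 2 * v for k, v in p_diff.items())
    de = -sum(v * ln(v) for v in p_diff.values())
    ent = -sum(P[i, j] * ln(P[i, j]) for i in range(ng) for j in range(ng))
    return {
        "asm": asm, "contrast": contrast, "correlation": corr,
        "sum_of_squares": sos, "idm": idm, "sum_average": sa,
        "sum_variance": sv, "sum_entropy": se, "entropy": ent,
        "difference_variance": dv, "difference_entropy": de,
    }


def oracle_rlm(level_img: np.ndarray, mask: np.ndarray, angle: int, n_levels: int):
    """Brute-force run enumeration: find run starts, walk forward."""
    dr, dc = DIR_OFFSETS[angle]
    nr, nc = mask.shape
    max_run = max(nr, nc)
    R = np.zeros((n_levels, max_run))

    def inside(r, c):
        return 0 <= r < nr and 0 <= c < nc and mask[r, c]

    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            g = level_img[r, c]
            # run start: predecessor along the direction absent or different
            pr, pc = r - dr, c - dc
            if inside(pr, pc) and level_img[pr, pc] == g:
                continue
            length = 1
            rr, cc = r + dr, c + dc
            while inside(rr, cc) and level_img[rr, cc] == g:
                length += 1
                rr, cc = rr + dr, cc + dc
            R[g - 1, length - 1] += 1
    return R


def oracle_rlm_features(R: np.ndarray, n_pixels: int) -> dict:
    ng, lmax = R.shape
    total = R.sum()
    if total == 0:
        return {k: math.nan for k in ("sre", "lre", "gln", "rln", "fraction")}
    sre = sum(R[g, r] / (r + 1) ** 2 for g in range(ng) for r in range(lmax)) / total
    lre = sum(R[g, r] * (r + 1) ** 2 for g in range(ng) for r in range(lmax)) / total
    gln = sum(sum(R[g, :]) ** 2 for g in range(ng)) / total
    rln = sum(sum(R[:, r]) ** 2 for r in range(lmax)) / total
    return {"sre": sre, "lre": lre, "gln": gln, "rln": rln, "fraction": total / n_pixels}


def oracle_gradient(px: np.ndarray, mask: np.ndarray) -> dict:
    nr, nc = mask.shape
    gs = []
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            neigh = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            if any(not (0 <= rr < nr and 0 <= cc < nc and mask[rr, cc]) for rr, cc in neigh):
                continue
            g = math.sqrt((px[r + 1, c] - px[r - 1, c]) ** 2 + (px[r, c + 1] - px[r, c - 1]) ** 2) / 2
            gs.append(g)
    if not gs:
        return {k: math.nan for k in ("mean", "variance", "skewness", "kurtosis", "nonzero_fraction")}
    h = oracle_his(np.array(gs))
    return {
        "mean": h["mean"], "variance": h["variance"], "skewness": h["skewness"],
        "kurtosis": h["kurtosis"], "nonzero_fraction": sum(g > 0 for g in gs) / len(gs),
    }


ARM_NEIGHBOURS = ((0, -1), (-1, 0), (-1, -1), (-1, 1))


def oracle_arm(level_img: np.ndarray, mask: np.ndarray, min_pixels: int = 20) -> dict:
    nr, nc = mask.shape
    vals = [float(level_img[r, c]) for r in range(nr) for c in range(nc) if mask[r, c]]
    mean = sum(vals) / len(vals)
    rows, targets = [], []
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            ok = True
            feats = []
            for dr, dc in ARM_NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc and mask[rr, cc]):
                    ok = False
                    break
                feats.append(level_img[rr, cc] - mean)
            if ok:
                rows.append(feats)
                targets.append(level_img[r, c] - mean)
    if len(rows) < min_pixels:
        return {k: math.nan for k in ("theta1", "theta2", "theta3", "theta4", "sigma")}
    A = np.array(rows, dtype=float)
    y = np.array(targets, dtype=float)
    theta = np.linalg.pinv(A) @ y
    resid = y - A @ theta
    sigma = math.sqrt(sum(e**2 for e in resid) / len(resid))
    return {
        "theta1": theta[0], "theta2": theta[1], "theta3": theta[2], "theta4": theta[3],
        "sigma": sigma,
    }


def oracle_haar(px: np.ndarray, mask: np.ndarray, max_scale: int) -> dict:
    """Direct basis-pattern evaluation: each scale-s coefficient is
    (1/2^s) * sum over its 2^s x 2^s block of image times a +/-1 pattern."""
    out = {f"s{s}_{b}": math.nan for s in range(1, max_scale + 1) for b in ("LL", "LH", "HL", "HH")}
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return out
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    box_m = mask[r0:r1, c0:c1]
    if box_m.shape[0] < 2 or box_m.shape[1] < 2:
        return out
    roi_mean = px[mask].mean()
    W = np.where(box_m, px[r0:r1, c0:c1] - roi_mean, 0.0)
    h, w = W.shape
    for s in range(1, max_scale + 1):
        size = 2**s
        half = size // 2
        low = np.ones(size)
        high = np.concatenate([np.ones(half), -np.ones(half)])
        nbr, nbc = h // size, w // size
        if nbr == 0 or nbc == 0:
            break
        for band, (fy, fx) in {
            "LL": (low, low), "LH": (low, high), "HL": (high, low), "HH": (high, high),
        }.items():
            coeffs = []
            for u in range(nbr):
                for v in range(nbc):
                    block_m = box_m[u * size : (u + 1) * size, v * size : (v + 1) * size]
                    if not block_m.all():
                        continue
                    block = W[u * size : (u + 1) * size, v * size : (v + 1) * size]
                    coeff = 0.0
                    for p in range(size):
                        for q in range(size):
                            coeff += block[p, q] * fy[p] * fx[q]
                    coeffs.append(coeff / size)
            if coeffs:
                out[f"s{s}_{band}"] = sum(c**2 for c in coeffs) / len(coeffs)
    return out


def oracle_trace_perimeter(mask: np.ndarray, spacing=(1.0, 1.0)) -> float:
    """Moore boundary trace re-implemented with a directed-edge state walk."""
    nr, nc = mask.shape
    sr, sc = spacing
    # clockwise neighbour ring starting north
    ring = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

    def on(p):
        return 0 <= p[0] < nr and 0 <= p[1] < nc and mask[p[0], p[1]]

    rows, cols = np.nonzero(mask)
    top = rows.min()
    start = (int(top), int(cols[rows == top].min()))
    state0 = (start, 6)  # backtrack direction index pointing west
    length = 0.0
    state = state0
    first = True
    steps = 0
    while first or state != state0:
        first = False
        steps += 1
        assert steps <= 8 * len(rows) + 8, "oracle trace failed to close"
        (cur, back) = state
        moved = False
        for step in range(1, 9):
            idx = (back + step) % 8
            cand = (cur[0] + ring[idx][0], cur[1] + ring[idx][1])
            if on(cand):
                length += math.hypot(ring[idx][0] * sr, ring[idx][1] * sc)
                prev_idx = (idx - 1) % 8
                prev_cell = (cur[0] + ring[prev_idx][0], cur[1] + ring[prev_idx][1])
                back_dir = ring.index((prev_cell[0] - cand[0], prev_cell[1] - cand[1]))
                state = (cand, back_dir)
                moved = True
                break
        if not moved:
            return 0.0  # isolated pixel: no closed contour
    return length


def oracle_geometry(mask: np.ndarray, spacing=(1.0, 1.0)) -> dict:
    sr, sc = spacing
    n = int(mask.sum())
    area = n * sr * sc
    perimeter = oracle_trace_perimeter(mask, spacing)
    circ = 4 * math.pi * area / perimeter**2 if perimeter > 0 else math.nan
    pts = [(r * sr, c * sc) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    my = sum(p[0] for p in pts) / n
    mx = sum(p[1] for p in pts) / n
    syy = sum((p[0] - my) ** 2 for p in pts) / n
    sxx = sum((p[1] - mx) ** 2 for p in pts) / n
    sxy = sum((p[0] - my) * (p[1] - mx) for p in pts) / n
    tr, det = syy + sxx, syy * sxx - sxy**2
    disc = math.sqrt(max(tr**2 / 4 - det, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    elong = math.sqrt(max(l2, 0.0) / l1) if l1 > 0 else 1.0
    feret = max(
        math.hypot(a[0] - b[0], a[1] - b[1]) for a in pts for b in pts
    )
    return {"area": area, "perimeter": perimeter, "circularity": circ, "elongation": elong, "feret": feret}


# selection oracles -----------------------------------------------------------

def oracle_fisher(values, labels) -> float:
    classes = sorted(set(labels))
    groups = [[v for v, l in zip(values, labels) if l == c] for c in classes]
    n = len(values)
    m = sum(values) / n
    vb = sum(len(g) * (sum(g) / len(g) - m) ** 2 for g in groups) / n
    vw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups) / n
    if vw == 0:
        return math.inf if vb > 0 else 0.0
    return vb / vw


def oracle_poe(values, labels) -> float:
    classes = sorted(set(labels))
    uniq = sorted(set(values))
    if len(uniq) == 1:
        return 0.5
    n = len(values)
    best = n
    for t in [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]:
        for left_class in classes:
            right_class = classes[1] if left_class == classes[0] else classes[0]
            errs = sum(
                1
                for v, l in zip(values, labels)
                if (l != left_class) == (v <= t)  # wrong side
            )
            best = min(best, errs)
    return best / n
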