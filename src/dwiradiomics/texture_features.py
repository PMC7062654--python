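"""The seven texture-feature families computed on a single 2-D lesion ROI.

Families and conventions
------------------------
HIS   first-order histogram moments and percentiles of the quantized levels.
COM   gray-level co-occurrence matrices (symmetric, normalized) at distances
      1..5 and directions 0/45/90/135 degrees, with eleven Haralick features.
RLM   gray-level run-length matrices in the four directions with the classic
      Galloway descriptors.
GRAD  absolute gradient magnitude (central differences on raw intensities).
ARM   a four-neighbour causal autoregressive model fitted by least squares.
WAV   non-standard separable Haar wavelet subband energies; a coefficient
      enters a subband energy only if its full spatial support lies inside the
      mask ("fully-supported coefficient" rule).
GEO   lesion geometry: area, traced perimeter, circularity, elongation and
      maximal Feret diameter in physical units.

All entropy-type features use the natural logarithm with 0*log(0) := 0.
HIS, COM, RLM and ARM operate on mu+/-3sigma quantized levels; GRAD and WAV on
raw intensities.  Undefined features are reported as missing (NaN), never
dropped, so every lesion yields a vector over the same frozen catalogue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError, InvalidRoiError, UnknownFeatureError
from .io_formats import AnnotatedImage, Modality
from .preprocessing import QuantizedRoi, _as_mask_array, _as_pixel_array, normalize_roi

# ---------------------------------------------------------------------------
# Configuration and catalogue
# ---------------------------------------------------------------------------

#: Direction name (degrees) -> (row, col) unit offset.  Row axis points down,
#: so 45 degrees steps up-right in image coordinates.
DIRECTIONS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
)

RLM_FEATURE_NAMES = ("sre", "lre", "gln", "rln", "fraction")

HIS_FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "perc01",
    "perc10",
    "perc50",
    "perc90",
    "perc99",
)

GRAD_FEATURE_NAMES = ("mean", "variance", "skewness", "kurtosis", "nonzero_fraction")
ARM_FEATURE_NAMES = ("theta1", "theta2", "theta3", "theta4", "sigma")
WAV_SUBBANDS = ("LL", "LH", "HL", "HH")
GEO_FEATURE_NAMES = ("area", "perimeter", "circularity", "elongation", "feret")


@dataclass(frozen=True)
class GlcmSpec:
    """One co-occurrence matrix setting: pixel distance and direction."""

    distance: int = 1
    direction: int = 0

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("GLCM distance must be >= 1")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = DIRECTIONS[self.direction]
        return dr * self.distance, dc * self.distance


@dataclass(frozen=True)
class TextureConfig:
    """Tunable knobs of the feature extractor (quantization depths, specs)."""

    his_levels: int = 64
    glcm_levels: int = 64
    rlm_levels: int = 64
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    directions: tuple[int, ...] = (0, 45, 90, 135)
    wav_max_scale: int = 3
    arm_min_pixels: int = 20


@dataclass
class FeatureVector:
    """Ordered feature-name -> value mapping for one lesion.

    Missing (undefined) features are NaN.  ``provenance`` records the
    quantization depths and matrix specs that produced the values.
    """

    values: dict[str, float]
    lesion_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def feature_catalogue(config: TextureConfig = TextureConfig()) -> tuple[str, ...]:
    """The frozen, ordered catalogue of feature names for a configuration."""
    names: list[str] = [f"HIS_{n}" for n in HIS_FEATURE_NAMES]
    for d in config.glcm_distances:
        for ang in config.directions:
            names += [f"COM_d{d}_{ang}deg_{n}" for n in GLCM_FEATURE_NAMES]
    for ang in config.directions:
        names += [f"RLM_{ang}deg_{n}" for n in RLM_FEATURE_NAMES]
    names += [f"GRAD_{n}" for n in GRAD_FEATURE_NAMES]
    names += [f"ARM_{n}" for n in ARM_FEATURE_NAMES]
    for s in range(1, config.wav_max_scale + 1):
        names += [f"WAV_s{s}_{b}" for b in WAV_SUBBANDS]
    names += [f"GEO_{n}" for n in GEO_FEATURE_NAMES]
    return tuple(names)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0 * ln 0 := 0 convention."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population variance, skewness and excess kurtosis.

    Skewness/kurtosis are NaN for zero variance.
    """
    mean = float(values.mean())
    centered = values - mean
    var = float(np.mean(centered**2))
    if var == 0.0:
        return mean, var, math.nan, math.nan
    sd = math.sqrt(var)
    skew = float(np.mean(centered**3)) / sd**3
    kurt = float(np.mean(centered**4)) / sd**4 - 3.0
    return mean, var, skew, kurt


# ---------------------------------------------------------------------------
# HIS
# ---------------------------------------------------------------------------

def his_features(q: QuantizedRoi) -> dict[str, float]:
    """First-order statistics of the quantized level distribution."""
    lv = q.levels.astype(float)
    mean, var, skew, kurt = _moments(lv)
    p = np.percentile(lv, [1, 10, 50, 90, 99])
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "perc01": float(p[0]),
        "perc10": float(p[1]),
        "perc50": float(p[2]),
        "perc90": float(p[3]),
        "perc99": float(p[4]),
    }


# ---------------------------------------------------------------------------
# COM (GLCM)
# ---------------------------------------------------------------------------

def glcm(q: QuantizedRoi, spec: GlcmSpec) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix, or None when no pair exists.

    Ordered pixel pairs are counted in both opposite offsets (symmetrization)
    and divided by the total pair count, so entries sum to one.
    """
    dr, dc = spec.offset
    lv = q.level_image
    m = q.mask
    nr, nc = m.shape
    # source window such that (r+dr, c+dc) stays in bounds
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    src_m = m[r0:r1, c0:c1]
    dst_m = m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = src_m & dst_m
    if not valid.any():
        return None
    i = lv[r0:r1, c0:c1][valid] - 1
    j = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid] - 1
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Eleven Haralick descriptors of a normalized symmetric GLCM.

    Sum variance is taken about the sum average; correlation is missing when a
    marginal has zero variance.
    """
    P = np.asarray(P, dtype=float)
    if abs(P.sum() - 1.0) > 1e-8 or not np.allclose(P, P.T, atol=1e-10):
        raise ContractViolationError("GLCM must be normalized and symmetric")
    ng = P.shape[0]
    levels = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(levels, levels, indexing="ij")
    px = P.sum(axis=1)
    mu = float((levels * px).sum())
    var = float(((levels - mu) ** 2 * px).sum())

    asm = float((P**2).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    correlation = (
        (float((I * J * P).sum()) - mu * mu) / var if var > 0 else math.nan
    )
    sum_of_squares = float(((I - mu) ** 2 * P).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())

    sums = (I + J).astype(int).ravel()  # 2 .. 2*ng
    p_sum = np.bincount(sums, weights=P.ravel(), minlength=2 * ng + 1)
    k = np.arange(p_sum.size, dtype=float)
    sum_average = float((k * p_sum).sum())
    sum_variance = float(((k - sum_average) ** 2 * p_sum).sum())
    sum_entropy = -float(_xlogx(p_sum).sum())

    diffs = np.abs(I - J).astype(int).ravel()  # 0 .. ng-1
    p_diff = np.bincount(diffs, weights=P.ravel(), minlength=ng)
    kd = np.arange(p_diff.size, dtype=float)
    diff_mean = float((kd * p_diff).sum())
    difference_variance = float(((kd - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = -float(_xlogx(p_diff).sum())

    entropy = -float(_xlogx(P).sum())
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares": sum_of_squares,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
    }


# ---------------------------------------------------------------------------
# RLM
# ---------------------------------------------------------------------------

def _direction_lines(shape: tuple[int, int], direction: int) -> list[np.ndarray]:
    """Index arrays of every full grid line along a direction.

    Each line is a (len, 2) array of (row, col) in traversal order; consecutive
    entries differ by the direction's unit offset, so run contiguity only ever
    breaks at mask boundaries or level changes.
    """
    nr, nc = shape
    lines = []
    if direction == 0:
        for r in range(nr):
            lines.append(np.stack([np.full(nc, r), np.arange(nc)], axis=1))
    elif direction == 90:
        for c in range(nc):
            lines.append(np.stack([np.arange(nr), np.full(nr, c)], axis=1))
    elif direction == 45:  # step (-1, +1): along a line r + c is constant
        for s in range(nr + nc - 1):
            r = np.arange(min(s, nr - 1), max(0, s - nc + 1) - 1, -1)
            c = s - r
            lines.append(np.stack([r, c], axis=1))
    elif direction == 135:  # step (-1, -1): along a line r - c is constant
        for d in range(-(nc - 1), nr):
            r = np.arange(max(d, 0), min(nr - 1, nc - 1 + d) + 1)
            c = r - d
            lines.append(np.stack([r, c], axis=1)[::-1])
    else:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
    return lines


def rlm(q: QuantizedRoi, direction: int) -> np.ndarray:
    """Run-length matrix: entry (g-1, r-1) counts runs of level g, length r.

    Runs are maximal same-level pixel sequences along in-mask collinear
    segments; a run ends at a mask boundary or a level change.
    """
    lv = q.level_image
    m = q.mask
    max_run = max(m.shape)
    R = np.zeros((q.n_levels, max_run), dtype=float)
    for line in _direction_lines(m.shape, direction):
        rr, cc = line[:, 0], line[:, 1]
        inside = m[rr, cc]
        levels = lv[rr, cc]
        run_level, run_len = 0, 0
        for ins, g in zip(inside, levels):
            if ins and g == run_level:
                run_len += 1
            else:
                if run_len:
                    R[run_level - 1, run_len - 1] += 1
                run_level, run_len = (g, 1) if ins else (0, 0)
        if run_len:
            R[run_level - 1, run_len - 1] += 1
    return R


def rlm_features(R: np.ndarray, n_pixels: int) -> dict[str, float]:
    """Galloway run-length descriptors.

    ``fraction`` is the fraction of image in runs: total runs / pixel count.
    All are missing when the matrix holds no run.
    """
    R = np.asarray(R, dtype=float)
    total = R.sum()
    if total == 0:
        return {n: math.nan for n in RLM_FEATURE_NAMES}
    r = np.arange(1, R.shape[1] + 1, dtype=float)
    runs_per_length = R.sum(axis=0)
    runs_per_level = R.sum(axis=1)
    return {
        "sre": float((runs_per_length / r**2).sum() / total),
        "lre": float((runs_per_length * r**2).sum() / total),
        "gln": float((runs_per_level**2).sum() / total),
        "rln": float((runs_per_length**2).sum() / total),
        "fraction": float(total / n_pixels),
    }


# ---------------------------------------------------------------------------
# Absolute gradient
# ---------------------------------------------------------------------------

def gradient_features(image, mask) -> dict[str, float]:
    """Statistics of the absolute gradient magnitude over mask-interior pixels.

    g(i,j) = sqrt((x[i+1,j]-x[i-1,j])^2 + (x[i,j+1]-x[i,j-1])^2) / 2 on raw
    intensities, evaluated only where all four neighbours are inside the mask.
    """
    px = _as_pixel_array(image)
    m = _as_mask_array(mask)
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    )
    if not interior.any():
        return {n: math.nan for n in GRAD_FEATURE_NAMES}
    gr = np.zeros_like(px)
    gr[1:-1, 1:-1] = 0.5 * np.hypot(
        px[2:, 1:-1] - px[:-2, 1:-1], px[1:-1, 2:] - px[1:-1, :-2]
    )
    g = gr[interior]
    mean, var, skew, kurt = _moments(g)
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "nonzero_fraction": float(np.mean(g > 0)),
    }


# ---------------------------------------------------------------------------
# ARM (causal autoregressive model)
# ---------------------------------------------------------------------------

#: Causal neighbour offsets (row, col): west, north, north-west, north-east.
ARM_NEIGHBOURS = ((0, -1), (-1, 0), (-1, -1), (-1, 1))


def arm_fit(q: QuantizedRoi, min_pixels: int = 20) -> dict[str, float]:
    """Least-squares fit of a four-neighbour causal AR model on centered levels.

    x(i,j) = th1*x(i,j-1) + th2*x(i-1,j) + th3*x(i-1,j-1) + th4*x(i-1,j+1) + e.
    Rank-deficient systems take the minimum-norm solution; the family is
    missing when fewer than ``min_pixels`` pixels have all four causal
    neighbours inside the mask.
    """
    m = q.mask
    lv = q.level_image.astype(float)
    centered = np.where(m, lv - lv[m].mean(), 0.0)
    nr, nc = m.shape
    usable = m.copy()
    usable[0, :] = False
    usable[:, 0] = False
    usable[:, -1] = False
    for dr, dc in ARM_NEIGHBOURS:
        shifted = np.zeros_like(m)
        shifted[max(0, -dr) : nr - max(0, dr), max(0, -dc) : nc - max(0, dc)] = m[
            max(0, dr) : nr - max(0, -dr), max(0, dc) : nc - max(0, -dc)
        ]
        usable &= shifted
    rows, cols = np.nonzero(usable)
    if rows.size < min_pixels:
        return {n: math.nan for n in ARM_FEATURE_NAMES}
    y = centered[rows, cols]
    X = np.stack([centered[rows + dr, cols + dc] for dr, dc in ARM_NEIGHBOURS], axis=1)
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    return {
        "theta1": float(theta[0]),
        "theta2": float(theta[1]),
        "theta3": float(theta[2]),
        "theta4": float(theta[3]),
        "sigma": float(np.sqrt(np.mean(resid**2))),
    }


# ---------------------------------------------------------------------------
# WAV (Haar subband energies)
# ---------------------------------------------------------------------------

def haar_features(image, mask, max_scale: int = 3) -> dict[str, float]:
    """Haar subband energies per scale under the fully-supported-coefficient rule.

    The mask's bounding box is taken, the ROI mean removed (outside-mask pixels
    therefore contribute zero) and an orthonormal separable Haar decomposition
    applied; trailing odd rows/columns are dropped at each level.  Subband
    naming: the first letter filters the row axis, so HL is the
    vertical-difference subband (responds to horizontal edges).  Each energy is
    the mean squared coefficient over coefficients whose spatial support lies
    entirely inside the mask; a subband with no such coefficient is missing.
    """
    px = _as_pixel_array(image)
    m = _as_mask_array(mask)
    out = {f"s{s}_{b}": math.nan for s in range(1, max_scale + 1) for b in WAV_SUBBANDS}
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        return out
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    box_mask = m[r0:r1, c0:c1]
    if box_mask.shape[0] < 2 or box_mask.shape[1] < 2:
        return out
    A = np.where(box_mask, px[r0:r1, c0:c1] - px[m].mean(), 0.0)
    sup = box_mask.copy()
    s2 = math.sqrt(2.0)
    for s in range(1, max_scale + 1):
        h2, w2 = A.shape[0] // 2, A.shape[1] // 2
        if h2 == 0 or w2 == 0:
            break
        A = A[: 2 * h2, : 2 * w2]
        sup_t = sup[: 2 * h2, : 2 * w2]
        L0 = (A[0::2] + A[1::2]) / s2   # low-pass along rows (axis 0)
        H0 = (A[0::2] - A[1::2]) / s2   # high-pass along rows
        sup0 = sup_t[0::2] & sup_t[1::2]
        bands = {
            "LL": (L0[:, 0::2] + L0[:, 1::2]) / s2,
            "LH": (L0[:, 0::2] - L0[:, 1::2]) / s2,
            "HL": (H0[:, 0::2] + H0[:, 1::2]) / s2,
            "HH": (H0[:, 0::2] - H0[:, 1::2]) / s2,
        }
        sup2 = sup0[:, 0::2] & sup0[:, 1::2]
        if sup2.any():
            for name, band in bands.items():
                out[f"s{s}_{name}"] = float(np.mean(band[sup2] ** 2))
        A = bands["LL"]
        sup = sup2
    return out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_MOORE_OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Closed 8-connected boundary path through pixel centers (Moore tracing).

    Starts at the topmost-then-leftmost pixel and walks clockwise; the
    returned path ends where it starts, so consecutive-point distances sum to
    the contour length.
    """
    m = _as_mask_array(mask)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise InvalidRoiError("cannot trace an empty mask")
    top = rows.min()
    start = (int(top), int(cols[rows == top].min()))
    nr, nc = m.shape

    def is_set(p):
        return 0 <= p[0] < nr and 0 <= p[1] < nc and m[p]

    boundary = [start]
    prev = (start[0], start[1] - 1)  # guaranteed outside
    cur = start
    first_move = None
    while True:
        d = _MOORE_OFFSETS.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for i in range(1, 9):
            off = _MOORE_OFFSETS[(d + i) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if is_set(cand):
                back_off = _MOORE_OFFSETS[(d + i - 1) % 8]
                nxt = cand
                new_prev = (cur[0] + back_off[0], cur[1] + back_off[1])
                break
        if nxt is None:  # isolated pixel
            return boundary
        if len(boundary) > 1 and cur == start and nxt == first_move:
            break  # Jacob's stopping criterion
        if first_move is None:
            first_move = nxt
        boundary.append(nxt)
        cur, prev = nxt, new_prev
        if len(boundary) > 8 * rows.size:  # safety; cannot occur on valid masks
            raise InvalidRoiError("boundary tracing did not terminate")
    if boundary[-1] != start:
        boundary.append(start)
    return boundary


def geometry_features(mask, spacing: tuple[float, float] = (1.0, 1.0)) -> dict[str, float]:
    """Area, perimeter, circularity, elongation and maximal Feret diameter.

    Area is pixel count times pixel area (mm^2); the perimeter is the length
    of the traced 8-connected boundary path through pixel centers (mm);
    circularity = 4*pi*area/perimeter^2; elongation is the minor/major axis
    ratio from second-order central moments of the pixel centers; the Feret
    diameter is the largest pixel-center distance (mm).
    """
    m = _as_mask_array(mask)
    sr, sc = float(spacing[0]), float(spacing[1])
    n = int(m.sum())
    area = n * sr * sc

    path = trace_boundary(m)
    pts = np.asarray(path, dtype=float)
    steps = np.diff(pts, axis=0)
    perimeter = float(np.hypot(steps[:, 0] * sr, steps[:, 1] * sc).sum())
    circularity = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else math.nan

    rows, cols = np.nonzero(m)
    coords = np.stack([rows * sr, cols * sc], axis=1)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))
    elongation = float(np.sqrt(eig[0] / eig[1])) if eig[1] > 0 else 1.0

    # the maximal pairwise distance is attained on the boundary
    edge = m & ~_erode8(m)
    er, ec = np.nonzero(edge)
    bpts = np.stack([er * sr, ec * sc], axis=1)
    diff = bpts[:, None, :] - bpts[None, :, :]
    feret = float(np.sqrt((diff**2).sum(axis=2)).max())
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": circularity,
        "elongation": elongation,
        "feret": feret,
    }


def _erode8(m: np.ndarray) -> np.ndarray:
    out = m.copy()
    out[0, :] = out[-1, :] = out[:, 0] = out[:, -1] = False
    inner = (
        m[1:-1, 1:-1]
        & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
        & m[:-2, :-2] & m[:-2, 2:] & m[2:, :-2] & m[2:, 2:]
    )
    out[1:-1, 1:-1] &= inner
    return out


# ---------------------------------------------------------------------------
# Full extraction and feature maps
# ---------------------------------------------------------------------------

def extract_all(image, mask, config: TextureConfig = TextureConfig(), lesion_id: str = "") -> FeatureVector:
    """Compute every catalogue feature for one lesion ROI.

    Quantization is performed per family depth; missing families or entries
    are NaN.  The output ordering is exactly :func:`feature_catalogue`.
    """
    px = _as_pixel_array(image)
    m = _as_mask_array(mask)
    spacing = image.spacing if isinstance(image, AnnotatedImage) else (1.0, 1.0)
    if not lesion_id and isinstance(image, AnnotatedImage):
        lesion_id = image.id

    quantized: dict[int, QuantizedRoi] = {}

    def q_for(n_levels: int) -> QuantizedRoi:
        if n_levels not in quantized:
            quantized[n_levels] = normalize_roi(px, m, n_levels)
        return quantized[n_levels]

    values: dict[str, float] = {}
    for k, v in his_features(q_for(config.his_levels)).items():
        values[f"HIS_{k}"] = v
    qg = q_for(config.glcm_levels)
    for d in config.glcm_distances:
        for ang in config.directions:
            P = glcm(qg, GlcmSpec(distance=d, direction=ang))
            feats = (
                glcm_features(P)
                if P is not None
                else {n: math.nan for n in GLCM_FEATURE_NAMES}
            )
            for k, v in feats.items():
                values[f"COM_d{d}_{ang}deg_{k}"] = v
    qr = q_for(config.rlm_levels)
    for ang in config.directions:
        for k, v in rlm_features(rlm(qr, ang), qr.n_pixels).items():
            values[f"RLM_{ang}deg_{k}"] = v
    for k, v in gradient_features(px, m).items():
        values[f"GRAD_{k}"] = v
    for k, v in arm_fit(q_for(config.glcm_levels), config.arm_min_pixels).items():
        values[f"ARM_{k}"] = v
    for k, v in haar_features(px, m, config.wav_max_scale).items():
        values[f"WAV_{k}"] = v
    for k, v in geometry_features(m, spacing).items():
        values[f"GEO_{k}"] = v

    catalogue = feature_catalogue(config)
    ordered = {name: values[name] for name in catalogue}
    provenance = {
        "his_levels": config.his_levels,
        "glcm_levels": config.glcm_levels,
        "rlm_levels": config.rlm_levels,
        "glcm_distances": list(config.glcm_distances),
        "directions": list(config.directions),
        "wav_max_scale": config.wav_max_scale,
        "arm_min_pixels": config.arm_min_pixels,
    }
    return FeatureVector(values=ordered, lesion_id=lesion_id, provenance=provenance)


def feature_map(
    image,
    mask,
    feature_name: str,
    window: int = 7,
    config: TextureConfig = TextureConfig(),
) -> AnnotatedImage:
    """Sliding-window recomputation of one feature, NaN outside the mask.

    At each mask pixel the feature is recomputed on the window-sized ROI
    clipped to the mask; windows on which the feature is undefined yield NaN.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if feature_name not in feature_catalogue(config):
        raise UnknownFeatureError(f"{feature_name!r} is not in the catalogue")
    px = _as_pixel_array(image)
    m = _as_mask_array(mask)
    half = window // 2
    out = np.full(px.shape, np.nan)
    rows, cols = np.nonzero(m)
    for r, c in zip(rows, cols):
        r0, r1 = max(0, r - half), min(px.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(px.shape[1], c + half + 1)
        sub_px = px[r0:r1, c0:c1]
        sub_m = m[r0:r1, c0:c1]
        if sub_m.sum() < 2:
            continue
        try:
            out[r, c] = _compute_single(sub_px, sub_m, feature_name, config)
        except (InvalidRoiError, ValueError):
            continue
    spacing = image.spacing if isinstance(image, AnnotatedImage) else (1.0, 1.0)
    return _map_image(out, spacing, feature_name)


def _map_image(out: np.ndarray, spacing, feature_name: str) -> AnnotatedImage:
    # AnnotatedImage requires finite pixels; NaN outside the mask is encoded
    # separately so the map still travels as a standard image + mask pair.
    img = AnnotatedImage(
        pixels=np.nan_to_num(out, nan=0.0),
        spacing=spacing,
        modality=Modality.ADC,
        id=f"map_{feature_name}",
    )
    object.__setattr__(img, "pixels", out)  # keep NaN sentinel outside mask
    return img


def _compute_single(px: np.ndarray, m: np.ndarray, name: str, config: TextureConfig) -> float:
    family, _, rest = name.partition("_")
    if family == "HIS":
        return his_features(normalize_roi(px, m, config.his_levels))[rest]
    if family == "COM":
        d_part, ang_part, feat = rest.split("_", 2)
        spec = GlcmSpec(distance=int(d_part[1:]), direction=int(ang_part[:-3]))
        P = glcm(normalize_roi(px, m, config.glcm_levels), spec)
        return math.nan if P is None else glcm_features(P)[feat]
    if family == "RLM":
        ang_part, feat = rest.split("_", 1)
        q = normalize_roi(px, m, config.rlm_levels)
        return rlm_features(rlm(q, int(ang_part[:-3])), q.n_pixels)[feat]
    if family == "GRAD":
        return gradient_features(px, m)[rest]
    if family == "ARM":
        return arm_fit(normalize_roi(px, m, config.glcm_levels), config.arm_min_pixels)[rest]
    if family == "WAV":
        return haar_features(px, m, config.wav_max_scale)[rest]
    if family == "GEO":
        return geometry_features(m)[rest]
    raise UnknownFeatureError(name)
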