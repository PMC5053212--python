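"""Independent naive reference implementations used only by the tests.

Everything here is written as directly as possible from the mathematical
definitions — explicit summation, pair enumeration, exhaustive search —
deliberately avoiding the vectorized/FFT code paths of the package, so the
two can check each other.
"""

from __future__ import annotations

import math

import numpy as np
import pywt
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon


# --------------------------------------------------------------------------
# thresholding oracles: exhaustive search over all candidate bins
# --------------------------------------------------------------------------

def otsu_exhaustive(counts: np.ndarray, edges: np.ndarray) -> float:
    """Minimize the weighted sum of within-class variances by brute force."""
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    best = (np.inf, None)
    for k in range(counts.size - 1):
        if counts[k] == 0:
            continue        # same class split as the previous occupied bin
        c0, c1 = counts[: k + 1], counts[k + 1:]
        n0, n1 = c0.sum(), c1.sum()
        if n0 == 0 or n1 == 0:
            continue
        m0 = (c0 * centers[: k + 1]).sum() / n0
        m1 = (c1 * centers[k + 1:]).sum() / n1
        v0 = (c0 * (centers[: k + 1] - m0) ** 2).sum() / n0
        v1 = (c1 * (centers[k + 1:] - m1) ** 2).sum() / n1
        crit = (n0 / total) * v0 + (n1 / total) * v1
        if crit < best[0]:
            best = (crit, k)
    return float(edges[best[1] + 1])


def kapur_exhaustive(counts: np.ndarray, edges: np.ndarray) -> float:
    """Maximize the summed entropies of the two classes by brute force."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts / total
    best = (-np.inf, None)
    for k in range(counts.size - 1):
        if counts[k] == 0:
            continue        # same class split as the previous occupied bin
        p0, p1 = p[: k + 1], p[k + 1:]
        w0, w1 = p0.sum(), p1.sum()
        if w0 == 0 or w1 == 0:
            continue
        q0 = p0[p0 > 0] / w0
        q1 = p1[p1 > 0] / w1
        h = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
        if h > best[0]:
            best = (h, k)
    return float(edges[best[1] + 1])


# --------------------------------------------------------------------------
# first-order statistics
# --------------------------------------------------------------------------

def moments(x) -> tuple[float, float, float, float]:
    x = [float(v) for v in np.asarray(x).ravel()]
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    return mu, m2, m3, m4


def skewness(x) -> float:
    _, m2, m3, _ = moments(x)
    return m3 / m2 ** 1.5


def kurtosis(x) -> float:
    _, m2, _, m4 = moments(x)
    return m4 / m2 ** 2


def entropy_bits(x, bins: int = 256) -> float:
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    h = 0.0
    for c in counts:
        if c > 0:
            pr = c / x.size
            h -= pr * math.log2(pr)
    return h


def histogram_features_oracle(values: np.ndarray, mask: np.ndarray,
                              bins: int = 256) -> dict:
    x = values[mask]
    mu, m2, m3, m4 = moments(x)
    xs = sorted(float(v) for v in x)
    return {
        "F37": mu,
        "F39": float(np.median(np.asarray(xs))),
        "F27": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "F18": m4,
        "F6": entropy_bits(x, bins),
        "F4": m4 / m2 ** 2 if m2 > 0 else 0.0,
        "F5": m3 / m2 ** 1.5 if m2 > 0 else 0.0,
    }


def gradient_skewness_oracle(values: np.ndarray, mask: np.ndarray) -> float:
    """Skewness of gradient magnitudes over interior dense pixels, by loops."""
    h, w = values.shape
    sample = []
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            if (mask[i, j] and mask[i - 1, j] and mask[i + 1, j]
                    and mask[i, j - 1] and mask[i, j + 1]):
                gx = (values[i, j + 1] - values[i, j - 1]) / 2.0
                gy = (values[i + 1, j] - values[i - 1, j]) / 2.0
                sample.append(math.hypot(gx, gy))
    return skewness(sample)


# --------------------------------------------------------------------------
# shape oracles: flood fill, explicit hull, explicit moments
# --------------------------------------------------------------------------

def _flood_components(mask: np.ndarray, connectivity: int) -> int:
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)
                if (a, b) != (0, 0)]
    else:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for a, b in nbrs:
                        rr, cc = r + a, c + b
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def count_blobs(mask: np.ndarray) -> int:
    return _flood_components(mask, 8)


def count_holes(mask: np.ndarray) -> int:
    """4-connected background components not touching the border."""
    mask = np.asarray(mask, bool)
    padded = np.pad(mask, 1)                    # border-touching bg merges
    total_bg = _flood_components(~padded, 4)
    return total_bg - 1


def euler_number_oracle(mask: np.ndarray) -> int:
    return count_blobs(mask) - count_holes(mask)


def perimeter_oracle(mask: np.ndarray) -> int:
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    per = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                for a, b in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = i + a, j + b
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        per += 1
    return per


def eccentricity_oracle(mask: np.ndarray) -> float:
    rr, cc = np.nonzero(mask)
    n = rr.size
    mr, mc = rr.mean(), cc.mean()
    urr = ((rr - mr) ** 2).sum() / n
    ucc = ((cc - mc) ** 2).sum() / n
    urc = ((rr - mr) * (cc - mc)).sum() / n
    tr = urr + ucc
    det = urr * ucc - urc ** 2
    disc = math.sqrt(max(0.0, tr ** 2 / 4 - det))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    if lam1 <= 0:
        return 0.0
    return math.sqrt(max(0.0, 1.0 - lam2 / lam1))


def solidity_oracle(mask: np.ndarray) -> float:
    """Area over convex-hull area, hull rasterized from pixel corner points."""
    rr, cc = np.nonzero(mask)
    corners = []
    for r, c in zip(rr, cc):
        corners += [(r - 0.5, c - 0.5), (r - 0.5, c + 0.5),
                    (r + 0.5, c - 0.5), (r + 0.5, c + 0.5)]
    pts = np.array(sorted(set(corners)))
    hull = ConvexHull(pts)
    poly = Polygon(pts[hull.vertices]).buffer(1e-9)
    inside = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if poly.contains(Point(i, j)):
                inside += 1
    return float(mask.sum()) / inside


# --------------------------------------------------------------------------
# projections
# --------------------------------------------------------------------------

def projection_kurtosis_oracle(values: np.ndarray) -> tuple[float, float]:
    rows = [sum(float(v) for v in values[i, :]) for i in range(values.shape[0])]
    cols = [sum(float(v) for v in values[:, j]) for j in range(values.shape[1])]
    return kurtosis(rows), kurtosis(cols)


# --------------------------------------------------------------------------
# transform oracles: explicit basis-matrix summation (no FFT)
# --------------------------------------------------------------------------

def dft_matrix(n: int) -> np.ndarray:
    j = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(j, j) / n)


def naive_dft2(x: np.ndarray) -> np.ndarray:
    h, w = x.shape
    return dft_matrix(h) @ x @ dft_matrix(w)


def naive_idft2(X: np.ndarray) -> np.ndarray:
    h, w = X.shape
    return (dft_matrix(h).conj() @ X @ dft_matrix(w).conj()) / (h * w)


def dct_matrix(n: int) -> np.ndarray:
    """Orthonormal DCT-II basis."""
    k = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    C = np.cos(np.pi * (2 * j + 1) * k / (2 * n))
    C[0, :] *= math.sqrt(1.0 / n)
    C[1:, :] *= math.sqrt(2.0 / n)
    return C


def naive_dct2(x: np.ndarray) -> np.ndarray:
    h, w = x.shape
    return dct_matrix(h) @ x @ dct_matrix(w).T


def local_range_oracle(v: np.ndarray, window: int) -> np.ndarray:
    h, w = v.shape
    half = window // 2
    out = np.empty_like(v)
    for i in range(h):
        for j in range(w):
            block = v[max(0, i - half): i + half + 1,
                      max(0, j - half): j + half + 1]
            out[i, j] = block.max() - block.min()
    return out


def hessian_det_oracle(v: np.ndarray) -> np.ndarray:
    h, w = v.shape
    def at(i, j):
        return v[i, j] if 0 <= i < h and 0 <= j < w else 0.0
    out = np.empty_like(v)
    for i in range(h):
        for j in range(w):
            dxx = at(i, j + 1) - 2 * at(i, j) + at(i, j - 1)
            dyy = at(i + 1, j) - 2 * at(i, j) + at(i - 1, j)
            dxy = (at(i + 1, j + 1) - at(i + 1, j - 1)
                   - at(i - 1, j + 1) + at(i - 1, j - 1)) / 4.0
            out[i, j] = dxx * dyy - dxy ** 2
    return out


def periodized_dwt_approx(x: np.ndarray, levels: int) -> np.ndarray:
    """Approximation band of the periodized 2-D db4 DWT by circular
    correlation (filter taps from the wavelet definition, transform done by
    explicit index arithmetic)."""
    h = np.array(pywt.Wavelet("db4").dec_lo)[::-1]
    L = len(h)

    def dwt1(sig: np.ndarray) -> np.ndarray:
        n = len(sig)
        out = np.empty(n // 2)
        for k in range(n // 2):
            acc = 0.0
            for m in range(L):
                acc += h[m] * sig[(2 * k - (L // 2 - 1) + m) % n]
            out[k] = acc
        return out

    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        a = np.apply_along_axis(dwt1, 1, a)
        a = np.apply_along_axis(dwt1, 0, a)
    return a


# --------------------------------------------------------------------------
# log-Gabor oracle (same filter definition, naive DFT mechanics)
# --------------------------------------------------------------------------

def log_gabor_filters_oracle(shape, frequencies, n_orient, sigma_ratio,
                             sigma_theta) -> list[np.ndarray]:
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fx ** 2 + fy ** 2)
    angle = np.arctan2(fy, fx)
    out = []
    for f0 in frequencies:
        radial = np.zeros(shape)
        nz = radius > 0
        radial[nz] = np.exp(-(np.log(radius[nz] / f0)) ** 2
                            / (2.0 * np.log(sigma_ratio) ** 2))
        for k in range(n_orient):
            theta = np.pi * k / n_orient
            d = np.arctan2(np.sin(angle - theta), np.cos(angle - theta))
            out.append(radial * np.exp(-d ** 2 / (2.0 * sigma_theta ** 2)))
    return out


def gabor_pooled_response_oracle(v: np.ndarray, frequencies, n_orient,
                                 sigma_ratio, sigma_theta) -> np.ndarray:
    spec = naive_dft2(v)
    filters = log_gabor_filters_oracle(v.shape, frequencies, n_orient,
                                       sigma_ratio, sigma_theta)
    pooled = np.zeros(v.shape, dtype=complex)
    for g in filters:
        pooled += naive_idft2(spec * g)
    return pooled / len(filters)


# --------------------------------------------------------------------------
# local entropy filter oracle
# --------------------------------------------------------------------------

def entropy_filter_oracle(v: np.ndarray, window: int, levels: int
                          ) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    h, w = v.shape
    out = np.zeros_like(v)
    if hi <= lo:
        return out
    q = np.minimum((v - lo) / (hi - lo) * levels, levels - 1).astype(int)
    half = window // 2
    for i in range(h):
        for j in range(w):
            block = q[max(0, i - half): i + half + 1,
                      max(0, j - half): j + half + 1].ravel()
            freq: dict[int, int] = {}
            for val in block:
                freq[int(val)] = freq.get(int(val), 0) + 1
            ent = 0.0
            for c in freq.values():
                p = c / block.size
                ent -= p * math.log2(p)
            out[i, j] = ent
    return out


# --------------------------------------------------------------------------
# co-occurrence oracle: explicit pair enumeration
# --------------------------------------------------------------------------

def glcm_oracle(values: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
                levels: int) -> np.ndarray | None:
    x = values[mask]
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        q = np.minimum((values - lo) / (hi - lo) * levels,
                       levels - 1).astype(int)
    else:
        q = np.zeros_like(values, dtype=int)
    dr, dc = offset
    h, w = values.shape
    mat = np.zeros((levels, levels))
    found = False
    for i in range(h):
        for j in range(w):
            ii, jj = i + dr, j + dc
            if ii < h and jj < w and mask[i, j] and mask[ii, jj]:
                mat[q[i, j], q[ii, jj]] += 1
                found = True
    if not found:
        return None
    mat = mat + mat.T
    return mat / mat.sum()


def glcm_entropy_bits(mat: np.ndarray) -> float:
    h = 0.0
    for p in mat.ravel():
        if p > 0:
            h -= p * math.log2(p)
    return h


# --------------------------------------------------------------------------
# singular values via the Gram matrix
# --------------------------------------------------------------------------

def singular_values_oracle(v: np.ndarray) -> np.ndarray:
    gram = v.T @ v if v.shape[0] >= v.shape[1] else v @ v.T
    eig = np.linalg.eigvalsh(gram)
    eig = np.clip(eig, 0.0, None)
    return np.sqrt(eig)[::-1]
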