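"""The 32 dense-area image features.

All features are computed from the identified dense area of a preprocessed
(normalized) mammogram.  Transform and texture operators act on the
*dense patch*: the tight bounding-box crop of the image with non-dense
pixels set to zero.  First-order statistics are taken over dense-pixel
intensities only.

The historical feature identifiers F1..F42 (with gaps) are kept so results
line up with the published feature table; names are exposed in
:data:`FEATURE_NAMES`.  Statistics use population moments (no small-sample
correction); entropies are Shannon entropies in bits.  A feature that is
undefined on a given input (zero variance, too-small patch, no valid pixel
pairs) is stored as 0.0 with an ``undefined`` flag, which the statistics
stage treats as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import fft as sp_fft
from scipy import ndimage
from skimage import measure, morphology

from .config import FEATURE_PARAMS, FeatureParams
from .image import DenseMask, MammogramImage

#: The 32 feature identifiers, in canonical order (numbering gaps preserved).
FEATURE_NAMES = (
    "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "F9", "F10",
    "F11", "F12", "F14", "F16", "F17", "F18", "F19", "F20", "F21", "F22",
    "F24", "F25", "F26", "F27", "F33", "F34", "F35", "F37", "F39", "F40",
    "F41", "F42",
)


@dataclass
class FeatureVector:
    """Named values of the 32 dense-area features for one image."""

    values: dict[str, float]
    flags: dict[str, bool]
    method: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"feature vector incomplete: missing {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> dict:
        row: dict = {"image_id": self.image_id, "method": self.method}
        row.update({k: self.values[k] for k in FEATURE_NAMES})
        row.update({f"{k}_undef": self.flags.get(k, False) for k in FEATURE_NAMES})
        return row


@dataclass
class DensePatch:
    """Tight crop of the dense area: values with non-dense pixels zeroed."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.mask.any():
            raise ValueError("dense patch must contain at least one dense pixel")

    @classmethod
    def from_image(cls, image: MammogramImage, dense: DenseMask | np.ndarray
                   ) -> "DensePatch":
        mask = dense.mask if isinstance(dense, DenseMask) else np.asarray(dense, bool)
        if not mask.any():
            raise ValueError("empty dense mask")
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
        sub_mask = mask[sl]
        sub_vals = np.where(sub_mask, np.asarray(image.pixels, float)[sl], 0.0)
        return cls(sub_vals, sub_mask)

    @property
    def dense_values(self) -> np.ndarray:
        return self.values[self.mask]


# --------------------------------------------------------------------------
# small numeric helpers
# --------------------------------------------------------------------------

def _central_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, m2, m3, m4) population central moments."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    d = x - mu
    return mu, float((d ** 2).mean()), float((d ** 3).mean()), float((d ** 4).mean())


def _degenerate(x: np.ndarray) -> bool:
    """All sample values identical (variance undefined up to rounding)."""
    x = np.asarray(x, dtype=float)
    return x.size == 0 or float(x.max()) == float(x.min())


def _skewness(x: np.ndarray) -> tuple[float, bool]:
    if _degenerate(x):
        return 0.0, True
    _, m2, m3, _ = _central_moments(x)
    if m2 <= 0:
        return 0.0, True
    return m3 / m2 ** 1.5, False


def _kurtosis(x: np.ndarray) -> tuple[float, bool]:
    """Pearson kurtosis m4 / m2^2 (not excess)."""
    if _degenerate(x):
        return 0.0, True
    _, m2, _, m4 = _central_moments(x)
    if m2 <= 0:
        return 0.0, True
    return m4 / m2 ** 2, False


def _entropy_bits(x: np.ndarray, bins: int) -> float:
    """Shannon entropy (bits) of the binned sample; constant sample -> 0."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def _pad_to(values: np.ndarray, size: int) -> np.ndarray:
    """Zero-pad bottom/right so both dimensions are at least ``size``."""
    h, w = values.shape
    if h >= size and w >= size:
        return values
    return np.pad(values, ((0, max(0, size - h)), (0, max(0, size - w))))


# --------------------------------------------------------------------------
# feature groups
# --------------------------------------------------------------------------

def histogram_features(patch: DensePatch,
                       params: FeatureParams = FEATURE_PARAMS
                       ) -> tuple[dict, dict]:
    """First-order statistics of dense-pixel intensities.

    F4 kurtosis, F5 skewness, F6 histogram entropy (bits), F18 fourth
    central moment, F27 interquartile range, F37 mean, F39 median.
    """
    x = patch.dense_values
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {}
    if x.size < 2:
        for k in ("F4", "F5", "F6", "F18", "F27", "F37", "F39"):
            vals[k], flags[k] = 0.0, True
        vals["F37"] = vals["F39"] = float(x[0]) if x.size else 0.0
        flags["F37"] = flags["F39"] = x.size == 0
        return vals, flags
    mu, m2, m3, m4 = _central_moments(x)
    vals["F37"], flags["F37"] = mu, False
    vals["F39"], flags["F39"] = float(np.median(x)), False
    q1, q3 = np.percentile(x, [25, 75])
    vals["F27"], flags["F27"] = float(q3 - q1), False
    vals["F18"], flags["F18"] = m4, False
    vals["F6"], flags["F6"] = _entropy_bits(x, params.histogram_bins), False
    if _degenerate(x) or m2 <= 0:
        vals["F4"], flags["F4"] = 0.0, True
        vals["F5"], flags["F5"] = 0.0, True
    else:
        vals["F4"], flags["F4"] = m4 / m2 ** 2, False
        vals["F5"], flags["F5"] = m3 / m2 ** 1.5, False
    return vals, flags


def gradient_skewness(patch: DensePatch) -> tuple[float, bool]:
    """F40 — skewness of the gradient-magnitude distribution.

    Gradients by central differences on the zero-filled patch; the sample is
    restricted to interior dense pixels — those whose four neighbors are
    dense — so the statistic measures the texture of the dense tissue
    itself (fatty-streak interspersion) rather than the geometry of the
    region outline, whose artificial zero-fill edges would otherwise
    dominate the tail of the gradient distribution.
    """
    v = patch.values
    m = patch.mask
    h, w = v.shape
    if h < 3 or w < 3:
        return 0.0, True
    gx = (v[1:-1, 2:] - v[1:-1, :-2]) / 2.0
    gy = (v[2:, 1:-1] - v[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    sel = (m[1:-1, 1:-1] & m[1:-1, 2:] & m[1:-1, :-2]
           & m[2:, 1:-1] & m[:-2, 1:-1])
    if sel.sum() < 3:
        return 0.0, True
    return _skewness(mag[sel])


def shape_features(mask: np.ndarray) -> tuple[dict, dict]:
    """Region shape descriptors of the (possibly disconnected) dense mask.

    F19 number of 8-connected blobs; F20 solidity (area over convex-hull
    area, pooled); F21 eccentricity of the ellipse with the same second
    central moments as the pooled dense pixel set — the focal distance over
    the major axis, sqrt(1 - lambda2/lambda1); F22 Euler number; F26 number
    of holes (F19 - F22); F35 total perimeter as the count of exposed pixel
    edges.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {k: False for k in
                              ("F19", "F20", "F21", "F22", "F26", "F35")}
    labels, n_blobs = ndimage.label(mask, structure=np.ones((3, 3), int))
    vals["F19"] = float(n_blobs)
    hull = morphology.convex_hull_image(mask)
    vals["F20"] = float(mask.sum()) / float(hull.sum())
    # pooled second-moment ellipse over all dense pixels
    rr, cc = np.nonzero(mask)
    pts = np.stack([rr, cc]).astype(float)
    cov = np.cov(pts, bias=True) if rr.size > 1 else np.zeros((2, 2))
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if lam[0] <= 0:
        vals["F21"], flags["F21"] = 0.0, True
    else:
        vals["F21"] = float(np.sqrt(max(0.0, 1.0 - lam[1] / lam[0])))
    euler = int(measure.euler_number(mask, connectivity=2))
    vals["F22"] = float(euler)
    vals["F26"] = float(n_blobs - euler)
    # exposed edges: mask pixel faces adjacent to background or the border
    per = 0
    padded = np.pad(mask, 1)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
        per += int((padded & ~nb).sum())
    vals["F35"] = float(per)
    return vals, flags


def projection_features(patch: DensePatch) -> tuple[dict, dict]:
    """F33/F34 — kurtosis of the row (Y) and column (X) intensity projections."""
    v = patch.values
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {}
    rows = v.sum(axis=1)
    cols = v.sum(axis=0)
    for key, prof in (("F33", rows), ("F34", cols)):
        if prof.size < 2:
            vals[key], flags[key] = 0.0, True
        else:
            vals[key], flags[key] = _kurtosis(prof)
    return vals, flags


def _hessian_determinant(v: np.ndarray) -> np.ndarray:
    """Determinant of the Hessian from second central differences (unit
    scale, zero padding)."""
    p = np.pad(v, 1)
    dxx = p[1:-1, 2:] - 2 * v + p[1:-1, :-2]
    dyy = p[2:, 1:-1] - 2 * v + p[:-2, 1:-1]
    dxy = (p[2:, 2:] - p[2:, :-2] - p[:-2, 2:] + p[:-2, :-2]) / 4.0
    return dxx * dyy - dxy ** 2


def _local_range(v: np.ndarray, window: int) -> np.ndarray:
    """Max-minus-min over a clipped square window."""
    mx = ndimage.maximum_filter(v, size=window, mode="constant", cval=-np.inf)
    mn = ndimage.minimum_filter(v, size=window, mode="constant", cval=np.inf)
    return mx - mn


def wavelet_level(shape: tuple[int, int], params: FeatureParams = FEATURE_PARAMS
                  ) -> int:
    """Decomposition depth for F2: requested depth capped by what the patch
    supports."""
    flen = pywt.Wavelet(params.wavelet).dec_len
    return max(1, min(params.wavelet_levels,
                      pywt.dwt_max_level(min(shape), flen)))


def transform_features(patch: DensePatch,
                       params: FeatureParams = FEATURE_PARAMS
                       ) -> tuple[dict, dict]:
    """Global transform coefficients of the zero-filled dense patch.

    F1 DC coefficient of the orthonormal 2-D DCT; F2 mean of the level-L
    approximation band of the 2-D DWT (Daubechies-4, periodized, L capped by
    patch size); F3 max DFT magnitude of the local-range-filtered patch;
    F11 max DFT magnitude excluding the DC bin; F14 max DFT magnitude of the
    Hessian-determinant response; F16 max of log(1+|DCT|); F17 max of
    log(1+|DFT|) excluding DC.

    The DC bin is excluded for F11/F17 (otherwise the maximum is trivially
    the image sum) but kept for F3/F14, whose inputs are filtered images
    where the DC term is informative.
    """
    v = _pad_to(patch.values, 8)
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {k: False for k in
                              ("F1", "F2", "F3", "F11", "F14", "F16", "F17")}
    dct = sp_fft.dctn(v, type=2, norm="ortho")
    vals["F1"] = float(dct[0, 0])
    vals["F16"] = float(np.log1p(np.abs(dct)).max())

    level = wavelet_level(v.shape, params)
    # zero-pad to a multiple of 2^level so each periodized stage has even
    # length (no wrap-around sample duplication)
    mult = 2 ** level
    vw = np.pad(v, ((0, -v.shape[0] % mult), (0, -v.shape[1] % mult)))
    with warnings.catch_warnings():
        # periodized DWT is well defined at this depth; pywt warns about
        # boundary effects on small inputs
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(vw, params.wavelet, mode="periodization",
                               level=level)
    vals["F2"] = float(np.asarray(coeffs[0]).mean())

    spec = np.abs(np.fft.fft2(v))
    nodc = spec.copy()
    nodc[0, 0] = 0.0
    vals["F11"] = float(nodc.max())
    vals["F17"] = float(np.log1p(nodc).max())
    vals["F3"] = float(np.abs(np.fft.fft2(_local_range(v, params.range_window))).max())
    vals["F14"] = float(np.abs(np.fft.fft2(_hessian_determinant(v))).max())
    return vals, flags


def log_gabor_bank(shape: tuple[int, int],
                   params: FeatureParams = FEATURE_PARAMS) -> list[np.ndarray]:
    """Frequency-domain log-Gabor filters (scales x orientations).

    Radial term exp(-(log(f/f0))^2 / (2 log(sigma_ratio)^2)) with zero DC
    response; angular term a wrapped Gaussian around each orientation.
    Filters are single-sided in orientation, so spatial responses are
    complex.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fx, fy)
    angle = np.arctan2(fy, fx)
    filters = []
    log_sr2 = 2.0 * np.log(params.gabor_sigma_ratio) ** 2
    for f0 in params.gabor_frequencies:
        with np.errstate(divide="ignore"):
            radial = np.exp(-(np.log(np.where(radius > 0, radius, 1.0) / f0)) ** 2
                            / log_sr2)
        radial[radius == 0] = 0.0
        for k in range(params.gabor_orientations):
            theta = np.pi * k / params.gabor_orientations
            d = np.arctan2(np.sin(angle - theta), np.cos(angle - theta))
            spread = np.exp(-d ** 2 / (2.0 * params.gabor_sigma_theta ** 2))
            filters.append(radial * spread)
    return filters


def gabor_entropy_features(patch: DensePatch,
                           params: FeatureParams = FEATURE_PARAMS
                           ) -> tuple[dict, dict]:
    """F8/F9/F10 — entropies of the pooled log-Gabor response.

    The patch is convolved (via the FFT) with the log-Gabor bank; complex
    responses are averaged over the bank; the Shannon entropy of the
    imaginary part, real part and magnitude over dense pixels gives
    F8, F9, F10.
    """
    v = _pad_to(patch.values, 16)
    mask = _pad_to(patch.mask.astype(float), 16) > 0.5
    spec = np.fft.fft2(v)
    pooled = np.zeros_like(spec)
    bank = log_gabor_bank(v.shape, params)
    for g in bank:
        pooled += np.fft.ifft2(spec * g)
    pooled /= len(bank)
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {}
    sel = mask
    for key, resp in (("F8", pooled.imag), ("F9", pooled.real),
                      ("F10", np.abs(pooled))):
        x = resp[sel]
        if x.size < 2:
            vals[key], flags[key] = 0.0, True
        else:
            vals[key], flags[key] = _entropy_bits(x, params.histogram_bins), False
    return vals, flags


def entropy_filter_feature(patch: DensePatch,
                           params: FeatureParams = FEATURE_PARAMS
                           ) -> tuple[float, bool]:
    """F7 — mean of the local-entropy-filtered patch over dense pixels.

    Local entropy (bits) of the quantized intensities in a clipped square
    window around each pixel.
    """
    v = patch.values
    h, w = v.shape
    win = params.entropy_window
    if h < win or w < win:
        return 0.0, True
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return 0.0, False      # constant patch: local entropy is 0 everywhere
    levels = params.histogram_bins
    q = np.minimum((v - lo) / (hi - lo) * levels, levels - 1).astype(np.int64)
    half = win // 2
    ent = np.empty_like(v)
    for i in range(h):
        i0, i1 = max(0, i - half), min(h, i + half + 1)
        for j in range(w):
            j0, j1 = max(0, j - half), min(w, j + half + 1)
            block = q[i0:i1, j0:j1].ravel()
            counts = np.bincount(block, minlength=0)
            p = counts[counts > 0] / block.size
            ent[i, j] = -(p * np.log2(p)).sum()
    return float(ent[patch.mask].mean()), False


def cooccurrence_features(patch: DensePatch,
                          params: FeatureParams = FEATURE_PARAMS
                          ) -> tuple[dict, dict]:
    """F12/F41/F42 — gray-level co-occurrence summaries.

    Intensities of dense pixels are quantized to ``glcm_levels`` levels;
    pairs are counted only when both pixels are dense; matrices are
    symmetrized and normalized to sum 1.  F12 is the entropy (bits) of the
    offset-(0,1) matrix; F41 the energy at offset (0,2); F42 the energy at
    offset (8,8).
    """
    v = patch.values
    mask = patch.mask
    x = patch.dense_values
    lo, hi = float(x.min()), float(x.max())
    levels = params.glcm_levels
    if hi > lo:
        q = np.minimum((v - lo) / (hi - lo) * levels, levels - 1).astype(np.int64)
    else:
        q = np.zeros_like(v, dtype=np.int64)
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {}
    specs = (("F12", (0, 1), "entropy"), ("F41", (0, 2), "energy"),
             ("F42", (8, 8), "energy"))
    h, w = v.shape
    for key, (dr, dc), kind in specs:
        if h <= dr or w <= dc:
            vals[key], flags[key] = 0.0, True
            continue
        a_m = mask[: h - dr, : w - dc]
        b_m = mask[dr:, dc:]
        both = a_m & b_m
        if not both.any():
            vals[key], flags[key] = 0.0, True
            continue
        a = q[: h - dr, : w - dc][both]
        b = q[dr:, dc:][both]
        mat = np.zeros((levels, levels))
        np.add.at(mat, (a, b), 1.0)
        mat = mat + mat.T
        mat /= mat.sum()
        if kind == "entropy":
            p = mat[mat > 0]
            vals[key] = float(-(p * np.log2(p)).sum())
        else:
            vals[key] = float((mat ** 2).sum())
        flags[key] = False
    return vals, flags


def svd_features(patch: DensePatch) -> tuple[dict, dict]:
    """F24/F25 — summaries of the normalized singular-value spectrum.

    Singular values of the zero-filled patch matrix are normalized to sum 1;
    F25 is the largest normalized singular value; F24 the skewness of the
    normalized spectrum divided by its standard deviation.
    """
    v = patch.values
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {}
    s = np.linalg.svd(v, compute_uv=False)
    tot = s.sum()
    if tot <= 0:
        return {"F24": 0.0, "F25": 0.0}, {"F24": True, "F25": True}
    ns = s / tot
    vals["F25"], flags["F25"] = float(ns[0]), False
    if ns.size < 3:
        vals["F24"], flags["F24"] = 0.0, True
    else:
        _, m2, m3, _ = _central_moments(ns)
        if m2 <= 0:
            vals["F24"], flags["F24"] = 0.0, True
        else:
            sd = m2 ** 0.5
            vals["F24"], flags["F24"] = (m3 / m2 ** 1.5) / sd, False
    return vals, flags


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def extract_features(image: MammogramImage, dense: DenseMask | np.ndarray,
                     params: FeatureParams = FEATURE_PARAMS) -> FeatureVector:
    """Assemble the full 32-entry feature vector for one image + dense mask.

    Deterministic; features that are undefined on the input are stored as
    0.0 with their ``undefined`` flag set (these are treated as missing by
    the statistics stage).
    """
    patch = DensePatch.from_image(image, dense)
    mask_full = dense.mask if isinstance(dense, DenseMask) else np.asarray(dense, bool)
    method = dense.method if isinstance(dense, DenseMask) else ""

    values: dict[str, float] = {}
    flags: dict[str, bool] = {}

    def absorb(v: dict, f: dict) -> None:
        values.update(v)
        flags.update(f)

    absorb(*histogram_features(patch, params))
    f40, fl40 = gradient_skewness(patch)
    values["F40"], flags["F40"] = f40, fl40
    absorb(*shape_features(mask_full))
    absorb(*projection_features(patch))
    absorb(*transform_features(patch, params))
    absorb(*gabor_entropy_features(patch, params))
    f7, fl7 = entropy_filter_feature(patch, params)
    values["F7"], flags["F7"] = f7, fl7
    absorb(*cooccurrence_features(patch, params))
    absorb(*svd_features(patch))
    return FeatureVector(values=values, flags=flags, method=method,
                         image_id=image.id)
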