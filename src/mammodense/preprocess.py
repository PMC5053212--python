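"""Pre-processing of raw mammograms.

Three deterministic steps, applied in a fixed order:

1. artifact removal — keep the largest connected bright component (the
   breast), zero out nametags and other off-breast artifacts;
2. intensity normalization — map the 1st/99th percentile of breast-pixel
   intensities to 0/1, reducing contrast differences between films;
3. pectoral-muscle removal — fit a straight-line boundary to the bright
   chest-wall-corner region and drop it from the breast mask.

Each step returns new objects; masks only ever shrink.  All operators are
flip-equivariant: mirroring the image (and flipping laterality) mirrors
every output.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .config import FOREGROUND_FRACTION, NORM_PERCENTILES
from .image import MammogramImage

logger = logging.getLogger(__name__)


class BlankImageError(ValueError):
    """Raised when an image has no foreground component."""


class DegenerateContrastError(ValueError):
    """Raised when the breast region has (near-)constant intensity."""


def remove_artifacts(image: MammogramImage,
                     foreground_fraction: float = FOREGROUND_FRACTION
                     ) -> tuple[MammogramImage, np.ndarray]:
    """Zero out everything except the largest connected bright component.

    Foreground is defined as pixels above ``foreground_fraction`` of the
    intensity range; the breast is its largest 8-connected component.
    Returns the cleaned image and the breast mask.
    """
    pix = np.asarray(image.pixels, dtype=float)
    thr = foreground_fraction * image.max_intensity
    fg = pix > thr
    if not fg.any():
        raise BlankImageError("no foreground component found")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    breast = labels == (1 + int(np.argmax(sizes)))
    cleaned = np.where(breast, pix, 0.0)
    return image.with_pixels(cleaned), breast


def normalize_intensity(image: MammogramImage, breast_mask: np.ndarray,
                        percentiles: tuple[float, float] = NORM_PERCENTILES
                        ) -> MammogramImage:
    """Rescale breast-pixel intensities so p1/p99 map to 0/1 (clipped).

    The map is monotone, so the ordering of breast pixels is preserved;
    pixels outside the mask stay 0.
    """
    pix = np.asarray(image.pixels, dtype=float)
    vals = pix[breast_mask]
    if vals.size == 0:
        raise BlankImageError("empty breast mask")
    lo, hi = np.percentile(vals, percentiles)
    if hi <= lo:
        raise DegenerateContrastError("breast region has constant intensity")
    out = np.clip((pix - lo) / (hi - lo), 0.0, 1.0)
    out[~breast_mask] = 0.0
    return image.with_pixels(out)


def _pectoral_candidates(pix: np.ndarray, breast: np.ndarray
                         ) -> np.ndarray | None:
    """Bright chest-wall-corner component in the upper-left quadrant.

    Assumes the chest wall is along column 0 (left laterality).  Returns a
    boolean mask of candidate pectoral pixels, or None when no plausible
    candidate exists.
    """
    h, w = pix.shape
    quad = np.zeros_like(breast)
    quad[: h // 2, : w // 2] = True
    region = breast & quad
    vals = pix[region]
    if vals.size < 20 or vals.max() <= vals.min():
        return None
    # split the quadrant's breast pixels into bright vs rest (Otsu on the
    # quadrant histogram); the pectoral muscle is the brightest structure
    hist, edges = np.histogram(vals, bins=128)
    thr = _otsu_from_counts(hist, edges)
    cand = region & (pix > thr)
    if not cand.any():
        return None
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    # keep the component hugging the chest wall at the top of the breast
    top_breast = int(np.flatnonzero(breast.any(axis=1))[0])
    for lab in range(1, n + 1):
        comp = labels == lab
        touches_wall = comp[:, 0].any()
        comp_top = int(np.flatnonzero(comp.any(axis=1))[0])
        if touches_wall and comp_top <= top_breast + 3:
            if comp.sum() >= 0.005 * breast.sum():
                return comp
    return None


def _otsu_from_counts(counts: np.ndarray, edges: np.ndarray) -> float:
    """Minimal Otsu on histogram counts; threshold at a bin upper edge."""
    counts = counts.astype(float)
    total = counts.sum()
    p = counts / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mt = m[-1]
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (mt * w0 - m) ** 2 / (w0 * w1)
    between[~valid] = -np.inf
    return float(edges[1:][int(np.argmax(between))])


def remove_pectoral(image: MammogramImage, breast_mask: np.ndarray
                    ) -> np.ndarray:
    """Remove the pectoral muscle from the breast mask.

    A straight line is fitted to the boundary of the bright chest-wall
    corner region (orientation set by laterality); everything on the chest
    wall side of the line, within the upper portion of the image, is
    dropped.  If no plausible pectoral region is found the mask is returned
    unchanged with a logged warning.
    """
    if image.view != "MLO":
        raise ValueError("pectoral removal is defined for MLO views only")
    pix = np.asarray(image.pixels, dtype=float)
    mask = np.asarray(breast_mask, dtype=bool)
    flip = image.laterality == "right"
    if flip:                     # canonicalize to chest wall on the left
        pix = pix[:, ::-1]
        mask = mask[:, ::-1]

    cand = _pectoral_candidates(pix, mask)
    if cand is None:
        logger.warning("no pectoral candidate found for image %r; "
                       "mask returned unchanged", image.id)
        return breast_mask

    # boundary points: rightmost candidate column in each row; a robust
    # (Theil-Sen) straight-line fit ignores sliver rows at the silhouette tip
    rows = np.flatnonzero(cand.any(axis=1))
    cols = np.array([np.flatnonzero(cand[r])[-1] for r in rows], dtype=float)
    if rows.size >= 2 and np.ptp(rows) > 0:
        rf = rows.astype(float)
        ii, jj = np.triu_indices(rows.size, k=1)
        keep = rf[jj] != rf[ii]
        slopes = (cols[jj] - cols[ii])[keep] / (rf[jj] - rf[ii])[keep]
        a = float(np.median(slopes))
        b = float(np.median(cols - a * rf))
    else:
        a, b = 0.0, float(cols.mean())
    h, w = pix.shape
    rr, cc = np.mgrid[0:h, 0:w]
    boundary_col = a * rr + b
    # small margin past the fitted line: the bright-core fit biases the
    # boundary inward, and residual pectoral pixels would contaminate the
    # dense mask downstream
    removed = (cc <= boundary_col + 2.5) & (rr <= rows[-1] + 4)
    out = mask & ~removed
    if flip:
        out = out[:, ::-1]
    return out & np.asarray(breast_mask, dtype=bool)


def preprocess_image(image: MammogramImage
                     ) -> tuple[MammogramImage, np.ndarray, dict]:
    """Full pre-processing chain: artifacts -> normalize -> pectoral.

    Returns the normalized image, the final breast mask (pectoral removed)
    and a small log dict of the steps applied.
    """
    cleaned, breast = remove_artifacts(image)
    normalized = normalize_intensity(cleaned, breast)
    final_mask = remove_pectoral(normalized, breast)
    log = {
        "id": image.id,
        "breast_pixels": int(breast.sum()),
        "final_pixels": int(final_mask.sum()),
        "pectoral_removed": int(breast.sum() - final_mask.sum()),
    }
    return normalized, final_mask, log
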