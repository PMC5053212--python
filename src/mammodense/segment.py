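"""Dense-area identification by histogram thresholding.

Three methods are supported, all operating on the intensity histogram of
breast-mask pixels (256 bins on the normalized [0, 1] scale by default):

- ``otsu``       — minimize the weighted sum of within-class variances;
- ``percentile`` — threshold at the p-th percentile (median by default);
- ``entropy``    — maximize the summed Shannon entropies of the two
  resulting classes (Kapur's maximum-entropy criterion).

Dense pixels are the breast pixels with intensity *strictly above* the
threshold; the dense area may consist of several disconnected parts.  A
dense-pixel fraction of the breast area is provided as a percent-density
proxy for synthetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HISTOGRAM_BINS
from .image import DenseMask, MammogramImage

METHODS = ("otsu", "percentile", "entropy")


class DegenerateHistogramError(ValueError):
    """Histogram with fewer than two occupied bins."""


@dataclass
class IntensityHistogram:
    """Counts of breast-pixel intensities over fixed bins on [0, 1]."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts and bin_edges sizes are inconsistent")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be nonnegative")

    @classmethod
    def from_image(cls, image: MammogramImage, breast_mask: np.ndarray,
                   bins: int = HISTOGRAM_BINS) -> "IntensityHistogram":
        vals = np.asarray(image.pixels, dtype=float)[np.asarray(breast_mask, bool)]
        counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
        return cls(counts, edges)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def n_occupied(self) -> int:
        return int((self.counts > 0).sum())


def threshold_otsu(hist: IntensityHistogram) -> float:
    """Otsu threshold: minimize the weighted within-class variance.

    Candidates are bin upper edges; the class split puts bins up to and
    including the candidate bin below, the rest above.  Ties are broken
    toward the lowest threshold.  Equivalent to maximizing the
    between-class variance.
    """
    if hist.n_occupied() < 2:
        raise DegenerateHistogramError("need >= 2 occupied bins")
    p = hist.counts / hist.total
    c = hist.centers
    w0 = np.cumsum(p)[:-1]          # candidate k: bins 0..k below
    w1 = 1.0 - w0
    s1 = np.cumsum(p * c)[:-1]      # class first moments
    s2 = np.cumsum(p * c * c)[:-1]
    t1, t2 = float(np.sum(p * c)), float(np.sum(p * c * c))
    # only occupied bins change the class split; restricting candidates to
    # them makes the tie-break (lowest threshold) well defined
    valid = (w0 > 0) & (w1 > 0) & (hist.counts[:-1] > 0)
    within = np.full(w0.shape, np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        # w0*var0 + w1*var1 with vark the within-class intensity variance
        within_val = (s2 - s1 ** 2 / w0) + ((t2 - s2) - (t1 - s1) ** 2 / w1)
    within[valid] = within_val[valid]
    k = int(np.argmin(within))      # argmin returns the first (lowest) tie
    return float(hist.bin_edges[k + 1])


def threshold_percentile(hist: IntensityHistogram, p: float = 50.0) -> float:
    """Threshold at the p-th percentile of the binned intensities.

    Returns the upper edge of the first bin whose cumulative count reaches
    ``p`` percent of the pixels; dense is strictly above it, so the dense
    fraction is at most ``1 - p/100``.
    """
    if hist.total == 0:
        raise DegenerateHistogramError("empty histogram")
    if not 0.0 <= p <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    cum = np.cumsum(hist.counts)
    k = int(np.searchsorted(cum, p / 100.0 * hist.total, side="left"))
    k = min(k, hist.counts.size - 1)
    return float(hist.bin_edges[k + 1])


def threshold_max_entropy(hist: IntensityHistogram) -> float:
    """Kapur maximum-entropy threshold.

    Maximizes the sum of Shannon entropies of the normalized below- and
    above-threshold sub-histograms (0 log 0 := 0); ties toward the lowest
    threshold.
    """
    if hist.n_occupied() < 2:
        raise DegenerateHistogramError("need >= 2 occupied bins")
    p = hist.counts / hist.total
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    s0 = np.cumsum(plogp)[:-1]
    s1 = float(plogp.sum()) - s0
    crit = np.full(w0.shape, -np.inf)
    valid = (w0 > 0) & (w1 > 0) & (hist.counts[:-1] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h0 = np.log(w0) - s0 / w0
        h1 = np.log(w1) - s1 / w1
    crit[valid] = (h0 + h1)[valid]
    k = int(np.argmax(crit))
    return float(hist.bin_edges[k + 1])


def dense_mask(image: MammogramImage, breast_mask: np.ndarray, method: str,
               bins: int = HISTOGRAM_BINS, percentile: float = 50.0
               ) -> DenseMask:
    """Dense-area mask: breast pixels strictly above the method's threshold.

    No morphological cleanup is applied; the dense area may be disconnected.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    hist = IntensityHistogram.from_image(image, breast_mask, bins=bins)
    if method == "otsu":
        thr = threshold_otsu(hist)
    elif method == "entropy":
        thr = threshold_max_entropy(hist)
    else:
        thr = threshold_percentile(hist, percentile)
    mask = np.asarray(breast_mask, bool) & (np.asarray(image.pixels, float) > thr)
    return DenseMask(mask=mask, method=method, threshold=thr)


def percent_density_proxy(dense: DenseMask | np.ndarray,
                          breast_mask: np.ndarray) -> float:
    """Dense-pixel percentage of the breast area.

    A documented stand-in for percent mammographic density on synthetic
    images; the clinical quantity is measured with dedicated area-based
    software and enters the statistics as an input covariate.
    """
    breast = np.asarray(breast_mask, bool)
    nb = int(breast.sum())
    if nb == 0:
        raise ValueError("empty breast mask")
    m = dense.mask if isinstance(dense, DenseMask) else np.asarray(dense, bool)
    return 100.0 * float(m.sum()) / nb
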