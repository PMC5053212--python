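"""Documented constants shared across the pipeline.

The intensity layout of the synthetic images and every unspecified filter
parameter of the feature bank live here, in one place, so that a run is fully
described by this module plus the explicit parameters of each call.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IntensityLayout:
    """Piecewise-constant intensity levels of the synthetic mammogram.

    Expressed as fractions of the full dynamic range (``2**bit_depth - 1``)
    and ordered ``background < fat < dense < pectoral <= nametag`` so that
    Otsu's method applied to the breast region separates dense from fatty
    tissue, and the pectoral muscle is the brightest anatomical structure.
    """

    background: float = 0.0
    fat: float = 0.30
    dense: float = 0.68
    pectoral: float = 0.84
    nametag: float = 0.95


#: Default intensity layout used by the simulator.
INTENSITY_LAYOUT = IntensityLayout()

#: Foreground threshold for artifact removal, as a fraction of the intensity
#: range.  Film digitizations have near-zero background, so 2% is robust.
FOREGROUND_FRACTION = 0.02

#: Percentiles used for inter-mammogram intensity normalization.
NORM_PERCENTILES = (1.0, 99.0)

#: Number of intensity histogram bins on the normalized [0, 1] scale.
HISTOGRAM_BINS = 256


@dataclass(frozen=True)
class FeatureParams:
    """Fixed defaults for every under-determined feature-bank parameter.

    The one-line feature definitions leave filter supports, wavelet family,
    quantization depths and the log-Gabor bank open; they are pinned here so
    feature values are reproducible and oracle-testable.
    """

    histogram_bins: int = 256          # first-order statistics + entropies
    glcm_levels: int = 32              # co-occurrence gray-level quantization
    wavelet: str = "db4"               # 2-D DWT family for F2
    wavelet_levels: int = 3            # decomposition depth for F2
    range_window: int = 3              # local range (max-min) filter for F3
    entropy_window: int = 9            # local entropy filter for F7
    gabor_frequencies: tuple[float, float] = (1 / 6, 1 / 12)  # cycles/pixel
    gabor_orientations: int = 4
    gabor_sigma_ratio: float = 0.65    # sigma_f / f0 of the log-Gabor radial term
    gabor_sigma_theta: float = 0.6547  # angular Gaussian width (radians)
    hessian_scale: int = 1             # central-difference Hessian, unit scale


FEATURE_PARAMS = FeatureParams()
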