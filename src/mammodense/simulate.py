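"""Synthetic mammogram-like images and synthetic cohorts with known truth.

Every downstream stage (preprocessing, dense-area segmentation, feature
extraction, case-case statistics) is testable against the ground truth this
module returns, with no external data.

The image generator draws a piecewise-constant phantom — background, fatty
breast tissue, a dense region, a pectoral triangle, an optional nametag —
then carves low-intensity fatty streaks through the dense region and adds
Gaussian noise.  The dense region is the superlevel set of an anisotropic
Gaussian blob field, so its area fraction is controlled exactly (by quantile
thresholding) and the elongation of its generating ellipse is controlled by
``dense_eccentricity``.

The cohort generator draws covariates from distributions matched to a
published case-case breast-cancer cohort (right-skewed percent density,
normal BMI and age, Bernoulli hormone-replacement use), latent standardized
image features, an interval-vs-screen-detected outcome from a logistic model
in those variables, and tumor sizes from stratum-specific linear models on
the square-root scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import INTENSITY_LAYOUT, IntensityLayout
from .image import MammogramImage


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class ImageSimParams:
    """Knobs of the synthetic mammogram generator.

    ``dense_fraction`` is the target fraction of breast pixels that are
    dense; ``dense_eccentricity`` the eccentricity of the generating ellipse
    of the dense blob; ``streak_intensity`` the relative depth (0 = none,
    1 = down to the fat level) of the fatty streaks carved through the dense
    region, which drives the skewness of the intensity-gradient
    distribution; ``noise_sd`` is in raw intensity units.
    """

    height: int = 192
    width: int = 160
    bit_depth: int = 12
    breast_axes: tuple[float, float] = (88.0, 100.0)   # (row, col) semi-axes
    pectoral_fraction: float = 0.15
    dense_fraction: float = 0.25
    dense_eccentricity: float = 0.5
    streak_intensity: float = 0.3
    noise_sd: float = 60.0
    nametag: bool = True
    laterality: str = "left"
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 < self.dense_fraction < 1.0:
            raise ValueError("dense_fraction must be in (0, 1)")
        if not 0.0 <= self.dense_eccentricity < 1.0:
            raise ValueError("dense_eccentricity must be in [0, 1)")
        if not 0.0 <= self.pectoral_fraction <= 0.3:
            raise ValueError("pectoral_fraction must be in [0, 0.3]")
        if self.streak_intensity < 0:
            raise ValueError("streak_intensity must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")


@dataclass
class CohortSimParams:
    """Generative coefficients of the synthetic case-case cohort.

    Log-odds coefficients are per standard deviation of the (sample
    standardized) covariate, except ``beta_hrt`` which is the log odds ratio
    for hormone-replacement use versus none.  Defaults reproduce the effect
    sizes of the motivating study: per-SD odds ratios of 1.32 for the latent
    gradient-skewness feature and 1.20 for the latent eccentricity feature,
    and square-root-scale tumor-size slopes of 0.20 (screen-detected stratum,
    first feature) and -0.18 (interval stratum, second feature).
    """

    n: int = 1403
    beta0: float = math.log(394 / 1009)      # marginal IC fraction ~0.28
    beta_pd: float = 0.0
    beta_hrt: float = 0.0
    beta_bmi: float = 0.0
    beta_age: float = 0.0
    beta_f40: float = math.log(1.32)
    beta_f21: float = math.log(1.20)
    gamma_sc_f40: float = 0.20
    gamma_ic_f21: float = -0.18
    missing_rates: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        for key, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {key!r} not in [0, 1]")


@dataclass
class GroundTruth:
    """Known truth accompanying a simulated image or cohort."""

    dense_mask: Optional[np.ndarray] = None
    pectoral_mask: Optional[np.ndarray] = None
    breast_mask: Optional[np.ndarray] = None
    coefficients: Optional[dict] = None


# --------------------------------------------------------------------------
# image generation
# --------------------------------------------------------------------------

def _breast_silhouette(h: int, w: int, axes: tuple[float, float]) -> np.ndarray:
    """Half-ellipse breast silhouette with the chest wall along column 0."""
    ar, ac = axes
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - h / 2.0) / ar) ** 2 + (cc / ac) ** 2 <= 1.0


def _pectoral_triangle(h: int, w: int, fraction: float) -> np.ndarray:
    """Right triangle at the top chest-wall corner; legs scale with fraction."""
    if fraction <= 0:
        return np.zeros((h, w), dtype=bool)
    rows = 2.0 * fraction * h
    cols = 2.0 * fraction * w
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr / rows + cc / cols) < 1.0


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _dense_blob_mask(breast: np.ndarray, pectoral: np.ndarray,
                     params: ImageSimParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Superlevel set of an anisotropic Gaussian blob field inside the breast.

    The quantile threshold is chosen so the mask holds ``dense_fraction`` of
    all breast pixels (pectoral pixels are never dense).
    """
    h, w = breast.shape
    allowed = breast & ~pectoral
    n_target = int(round(params.dense_fraction * breast.sum()))
    if n_target < 1 or n_target > 0.95 * allowed.sum():
        raise ValueError("dense region cannot fit the breast silhouette")

    # generating ellipse: axis ratio b/a = sqrt(1 - e^2); the major axis
    # runs roughly along the chest wall (with jitter) so elongated regions
    # are not clipped by the silhouette, which would blunt the requested
    # eccentricity
    ecc = params.dense_eccentricity
    ratio = math.sqrt(1.0 - ecc ** 2)
    theta = math.pi / 2 + rng.uniform(-0.35, 0.35)
    # center the blob inside the breast, clear of the pectoral corner
    r0 = 0.55 * h
    c0 = 0.42 * params.breast_axes[1]
    su = 0.40 * min(params.breast_axes) / math.sqrt(ratio)
    sv = su * ratio
    rr, cc = np.mgrid[0:h, 0:w]
    dr, dc = rr - r0, cc - c0
    u = math.cos(theta) * dc + math.sin(theta) * dr
    v = -math.sin(theta) * dc + math.cos(theta) * dr
    blob = np.exp(-0.5 * ((u / su) ** 2 + (v / sv) ** 2))
    # mild smooth perturbation makes the boundary blobby without moving the
    # second moments appreciably
    blob = blob + 0.004 * _smooth_noise((h, w), rng, sigma=3.0)

    vals = blob[allowed]
    thr = np.partition(vals, vals.size - n_target)[vals.size - n_target]
    mask = allowed & (blob >= thr)
    return mask


def _streak_mask(dense: np.ndarray, rng: np.random.Generator,
                 n_streaks: int = 3) -> np.ndarray:
    """Curvilinear streaks crossing the dense region's bounding box."""
    out = np.zeros_like(dense)
    rows = np.flatnonzero(dense.any(axis=1))
    cols = np.flatnonzero(dense.any(axis=0))
    if rows.size == 0:
        return out
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    h, w = dense.shape
    t = np.linspace(0.0, 1.0, 4 * max(r1 - r0, c1 - c0, 8))
    for _ in range(n_streaks):
        # a smooth sinusoidal curve running across the box
        phase = rng.uniform(0, 2 * math.pi)
        amp = rng.uniform(0.05, 0.2) * (c1 - c0 + 1)
        freq = rng.uniform(1.0, 2.5)
        offset = rng.uniform(0.2, 0.8)
        rr = r0 + t * (r1 - r0)
        cc = c0 + offset * (c1 - c0) + amp * np.sin(2 * math.pi * freq * t + phase)
        ri = np.clip(np.rint(rr), 0, h - 1).astype(int)
        ci = np.clip(np.rint(cc), 0, w - 1).astype(int)
        out[ri, ci] = True
    return out & dense


def generate_breast_image(params: ImageSimParams) -> tuple[MammogramImage, GroundTruth]:
    """Generate one synthetic mammogram plus its ground-truth masks.

    Deterministic given ``params.seed``.  The image is piecewise constant at
    the configured background/fat/dense/pectoral/nametag levels, with
    streaks carved through the dense region at relative depth
    ``streak_intensity`` and additive Gaussian noise of sd ``noise_sd``
    clipped to the dynamic range.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    vmax = 2 ** params.bit_depth - 1
    lay: IntensityLayout = INTENSITY_LAYOUT

    breast = _breast_silhouette(h, w, params.breast_axes)
    if not breast.any():
        raise ValueError("breast silhouette is empty; enlarge breast_axes")
    pectoral = _pectoral_triangle(h, w, params.pectoral_fraction) & breast
    dense = _dense_blob_mask(breast, pectoral, params, rng)

    img = np.full((h, w), lay.background * vmax)
    img[breast] = lay.fat * vmax
    img[dense] = lay.dense * vmax
    if params.streak_intensity > 0:
        depth = min(params.streak_intensity, 1.0)
        streaks = _streak_mask(dense, rng)
        img[streaks] = (lay.dense - depth * (lay.dense - lay.fat)) * vmax
    img[pectoral] = lay.pectoral * vmax

    if params.nametag:
        tag = np.zeros((h, w), dtype=bool)
        th, tw = max(6, h // 12), max(10, w // 6)
        tag[4:4 + th, w - tw - 4:w - 4] = True
        tag &= ~breast          # nametag never overlaps the breast
        img[tag] = lay.nametag * vmax

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, vmax).astype(np.uint16)

    image = MammogramImage(img, bit_depth=params.bit_depth,
                           laterality="left", id=f"sim-{params.seed}")
    if params.laterality == "right":
        image = image.mirrored()
        breast = breast[:, ::-1].copy()
        pectoral = pectoral[:, ::-1].copy()
        dense = dense[:, ::-1].copy()
    truth = GroundTruth(dense_mask=dense, pectoral_mask=pectoral,
                        breast_mask=breast)
    return image, truth


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

#: Column dictionary of the cohort table (one row per woman).
COHORT_COLUMNS = {
    "id": "record identifier",
    "outcome": "IC (interval cancer) or SC (screen-detected cancer)",
    "pd": "percent mammographic density (0-100)",
    "age_dx": "age at diagnosis, years",
    "bmi": "body mass index, kg/m^2",
    "hrt": "hormone replacement therapy during the year of diagnosis (yes/no)",
    "oc_use": "ever use of oral contraceptives (yes/no)",
    "menopausal": "menopausal at diagnosis (yes/no)",
    "parity_status": "nulliparous or parous",
    "births": "number of births (parous women)",
    "age_first_birth": "age at first birth, years (parous women)",
    "family_history": "first-degree family history of breast cancer (yes/no)",
    "er": "estrogen receptor status (positive/negative)",
    "pr": "progesterone receptor status (positive/negative)",
    "lymph_node": "lymph node metastasis (yes/no)",
    "grade": "Elston tumor grade (1/2/3)",
    "tumor_size": "pathological tumor size, mm",
    "months_to_dx": "months from pre-diagnostic mammogram to diagnosis",
    "f40": "latent standardized gradient-skewness feature",
    "f21": "latent standardized eccentricity feature",
}


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a case-case cohort table with known coefficients.

    Covariate distributions are matched to the reference cohort: percent
    density lognormal (median ~19%, right-skewed), BMI normal(25.5, 4),
    age normal(60.4, 7), HRT Bernoulli(0.19).  The interval-cancer indicator
    follows a logistic model in the sample-standardized covariates and the
    latent features; tumor size follows stratum-specific linear models on
    the square-root scale (floored at 1 mm after squaring).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    pd_pct = np.minimum(np.exp(rng.normal(math.log(19.0), 0.55, n)), 95.0)
    bmi = rng.normal(25.5, 4.0, n)
    age = rng.normal(60.4, 7.0, n)
    hrt = rng.random(n) < 0.19
    f40 = rng.standard_normal(n)
    f21 = rng.standard_normal(n)

    lp = (params.beta0
          + params.beta_pd * _standardize(pd_pct)
          + params.beta_hrt * hrt
          + params.beta_bmi * _standardize(bmi)
          + params.beta_age * _standardize(age)
          + params.beta_f40 * f40
          + params.beta_f21 * f21)
    ic = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))

    # square-root-scale tumor size, stratum-specific slopes
    sqrt_size = np.where(ic, 4.42, 3.95) + rng.normal(0.0, 1.3, n)
    sqrt_size = sqrt_size + np.where(ic, params.gamma_ic_f21 * f21,
                                     params.gamma_sc_f40 * f40)
    tumor_size = np.maximum(sqrt_size ** 2 * np.sign(sqrt_size), 1.0)

    months = np.where(ic, rng.uniform(2.0, 28.0, n),
                      np.clip(rng.normal(24.6, 4.0, n), 6.0, 40.0))

    parous = rng.random(n) < 0.845
    births = np.where(parous, rng.integers(1, 5, n), 0)
    afb = np.where(parous, rng.normal(25.5, 4.5, n), np.nan)

    table = pd.DataFrame({
        "id": [f"w{i:05d}" for i in range(n)],
        "outcome": np.where(ic, "IC", "SC"),
        "pd": pd_pct,
        "age_dx": age,
        "bmi": bmi,
        "hrt": np.where(hrt, "yes", "no"),
        "oc_use": np.where(rng.random(n) < 0.77, "yes", "no"),
        "menopausal": np.where(rng.random(n) < 0.83, "yes", "no"),
        "parity_status": np.where(parous, "parous", "nulliparous"),
        "births": births,
        "age_first_birth": afb,
        "family_history": np.where(rng.random(n) < 0.19, "yes", "no"),
        "er": np.where(rng.random(n) < 0.88, "positive", "negative"),
        "pr": np.where(rng.random(n) < 0.70, "positive", "negative"),
        "lymph_node": np.where(rng.random(n) < 0.06, "yes", "no"),
        "grade": rng.choice([1, 2, 3], size=n, p=[0.22, 0.53, 0.25]),
        "tumor_size": tumor_size,
        "months_to_dx": months,
        "f40": f40,
        "f21": f21,
    })

    for col, rate in params.missing_rates.items():
        if rate > 0:
            miss = rng.random(n) < rate
            if table[col].dtype.kind in "if":
                table.loc[miss, col] = np.nan
            else:
                table.loc[miss, col] = pd.NA

    truth = GroundTruth(coefficients={
        "beta0": params.beta0, "beta_pd": params.beta_pd,
        "beta_hrt": params.beta_hrt, "beta_bmi": params.beta_bmi,
        "beta_age": params.beta_age, "beta_f40": params.beta_f40,
        "beta_f21": params.beta_f21, "gamma_sc_f40": params.gamma_sc_f40,
        "gamma_ic_f21": params.gamma_ic_f21,
    })
    return table, truth
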