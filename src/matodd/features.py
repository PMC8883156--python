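"""Compressed color texture statistics for stimulus images.

Images are converted to CIE L*a*b* against a scene-specific white point,
center-cropped, and each channel is summarized by statistics of a complex
steerable pyramid decomposition (4 scales x 4 orientations, computed in the
frequency domain without subsampling): marginal moments, subband
autocorrelations, and within- and cross-scale magnitude correlations.  Each
channel's full statistic set is reduced to 32 named features through an
explicit registry; the color variant concatenates the three channels into a
96-entry vector.  Pixel-statistic subsets (3 color means; 12 color moments)
are also exposed.

Feature distances between the images of one task condition — the mean
pairwise Euclidean distance on per-feature z-scores, or per-feature mean
absolute differences — are the predictors for the sensitivity regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "LabImage",
    "FeatureVector",
    "VARIANTS",
    "rgb_to_lab",
    "linear_rgb_to_xyz",
    "center_crop",
    "steerable_pyramid",
    "compute_ps_statistics",
    "reduce_features",
    "extract_features",
    "feature_table",
    "zscore_columns",
    "mean_feature_distance",
    "per_feature_distances",
]

VARIANTS = ("color_means", "color_stats", "ps_gray", "ps_gray_plus_color", "ps_color")

#: fixed pyramid geometry
N_SCALES = 4
N_ORIENTATIONS = 4

# sRGB primaries, D65 (linear RGB -> XYZ)
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


@dataclass(frozen=True)
class LabImage:
    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    white_point: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return {"L": self.L, "a": self.a, "b": self.b}[name]


@dataclass(frozen=True)
class FeatureVector:
    variant: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values must align")
        expected = {"color_means": 3, "color_stats": 12, "ps_gray": 32, "ps_color": 96}
        if self.variant in expected and len(self.values) != expected[self.variant]:
            raise ValueError(
                f"variant {self.variant} requires {expected[self.variant]} "
                f"features, got {len(self.values)}"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


# ---------------------------------------------------------------------------
# color conversion

def linear_rgb_to_xyz(rgb_linear: np.ndarray) -> np.ndarray:
    return rgb_linear @ _RGB2XYZ.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def rgb_to_lab(image: np.ndarray, white_point: np.ndarray) -> LabImage:
    """8-bit sRGB (display gamma 2.2) to CIE L*a*b* under a scene white.

    The white point is the XYZ of the scene's diffuse white (a matte white
    sphere rendered under the same illumination), so L* = 100 corresponds to
    that surface rather than to a nominal display white.
    """
    white_point = np.asarray(white_point, dtype=float)
    if white_point.shape != (3,) or np.any(white_point <= 0):
        raise ValueError("white_point must be 3 strictly positive XYZ values")
    if image.ndim != 3 or image.shape[-1] != 3 or image.dtype != np.uint8:
        raise ValueError("image must be an 8-bit, 3-channel array")
    linear = (image.astype(float) / 255.0) ** 2.2
    xyz = linear_rgb_to_xyz(linear)
    fx, fy, fz = (_lab_f(xyz[..., i] / white_point[i]) for i in range(3))
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return LabImage(L=L, a=a, b=b, white_point=white_point)


def center_crop(image: np.ndarray, size: int = 128) -> np.ndarray:
    """Exact central window; odd margins put the extra pixel on bottom/right."""
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop {size}")
    top = (h - size) // 2
    left = (w - size) // 2
    return image[top : top + size, left : left + size]


# ---------------------------------------------------------------------------
# complex steerable pyramid (frequency-domain, no subsampling)

def _log_raised_cosine(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Lowpass mask: 1 below cutoff/2, 0 above cutoff, raised cosine between
    (in log2 frequency)."""
    out = np.zeros_like(r)
    out[r <= cutoff / 2] = 1.0
    band = (r > cutoff / 2) & (r < cutoff)
    with np.errstate(divide="ignore"):
        out[band] = np.cos(np.pi / 2 * (np.log2(r[band] / cutoff) + 1.0))
    return out


def _freq_polar(n: int):
    f = np.fft.fftfreq(n) * 2 * np.pi
    fx = f[None, :]
    fy = f[:, None]
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    return r, theta


def _angular_mask(theta: np.ndarray, k: int, n_orient: int) -> np.ndarray:
    """Single-sided cos^(K-1) angular window for orientation k."""
    th0 = np.pi * k / n_orient
    dth = np.mod(theta - th0 + np.pi, 2 * np.pi) - np.pi
    mask = np.zeros_like(theta)
    inside = np.abs(dth) < np.pi / 2
    mask[inside] = np.cos(dth[inside]) ** (n_orient - 1)
    return mask


def steerable_pyramid(
    plane: np.ndarray,
    n_scales: int = N_SCALES,
    n_orientations: int = N_ORIENTATIONS,
):
    """Complex oriented subbands plus the real lowpass residual.

    Returns (bands, lowpass) where ``bands[s][k]`` is the complex subband at
    scale s (coarser with increasing s) and orientation k, all at full
    resolution.  The image is treated as periodic (circular boundary
    handling), so statistics are exactly invariant to circular shifts.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("plane must be 2-D")
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane contains non-finite values")
    n = plane.shape[0]
    if plane.shape[1] != n:
        raise ValueError("plane must be square")
    F = np.fft.fft2(plane)
    r, theta = _freq_polar(n)
    bands: list[list[np.ndarray]] = []
    for s in range(n_scales):
        c_hi = np.pi / 2**s
        c_lo = np.pi / 2 ** (s + 1)
        radial = np.sqrt(
            np.clip(
                _log_raised_cosine(r, c_hi) ** 2
                * (1.0 - _log_raised_cosine(r, c_lo) ** 2),
                0.0,
                None,
            )
        )
        row = []
        for k in range(n_orientations):
            mask = radial * _angular_mask(theta, k, n_orientations)
            row.append(np.fft.ifft2(F * mask) * 2.0)  # single-sided doubling
        bands.append(row)
    low_mask = _log_raised_cosine(r, np.pi / 2**n_scales)
    lowpass = np.fft.ifft2(F * low_mask).real
    return bands, lowpass


# ---------------------------------------------------------------------------
# statistics

def _marginals(x: np.ndarray) -> dict[str, float]:
    m = float(x.mean())
    sd = float(x.std())
    if sd < 1e-12:
        return {"mean": m, "sd": 0.0, "skew": 0.0, "kurt": 0.0}
    return {
        "mean": m,
        "sd": sd,
        "skew": float(sstats.skew(x, axis=None)),
        "kurt": float(sstats.kurtosis(x, axis=None, fisher=False)),
    }


def _norm_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom < 1e-12:
        return 0.0
    return float((a * b).sum() / denom)


def _circular_autocorr(x: np.ndarray, lag: int) -> float:
    """Normalized circular autocorrelation, averaged over the two axes."""
    ac_r = _norm_corr(x, np.roll(x, lag, axis=0))
    ac_c = _norm_corr(x, np.roll(x, lag, axis=1))
    return 0.5 * (ac_r + ac_c)


def compute_ps_statistics(
    plane: np.ndarray,
    n_scales: int = N_SCALES,
    n_orientations: int = N_ORIENTATIONS,
) -> dict:
    """Full texture-statistics set for one channel plane.

    Families: pixel marginal moments; marginals of the lowpass residual;
    per-subband magnitude means; within-scale cross-orientation and
    adjacent-scale magnitude correlation matrices; per-scale band
    autocorrelations and real-part skewness.  A constant plane yields zeros
    for every variance-normalized statistic.
    """
    plane = np.asarray(plane, dtype=float)
    stats: dict = {"pixel": _marginals(plane)}
    if plane.std() < 1e-12:
        z = np.zeros((n_orientations, n_orientations))
        stats.update(
            lowpass={"mean": float(plane.mean()), "sd": 0.0, "skew": 0.0, "kurt": 0.0},
            lowpass_ac=np.zeros(3),
            mag_means=np.zeros((n_scales, n_orientations)),
            xori_corr=[z.copy() for _ in range(n_scales)],
            xscl_corr=[z.copy() for _ in range(n_scales - 1)],
            band_ac1=np.zeros(n_scales),
            band_skew=np.zeros(n_scales),
        )
        return stats

    bands, lowpass = steerable_pyramid(plane, n_scales, n_orientations)
    mags = [[np.abs(b) for b in row] for row in bands]
    reals = [[b.real for b in row] for row in bands]

    stats["lowpass"] = _marginals(lowpass)
    stats["lowpass_ac"] = np.array(
        [_circular_autocorr(lowpass, lag) for lag in (1, 2, 3)]
    )
    stats["mag_means"] = np.array(
        [[m.mean() for m in row] for row in mags]
    )
    stats["xori_corr"] = [
        np.array(
            [
                [_norm_corr(mags[s][i], mags[s][j]) for j in range(n_orientations)]
                for i in range(n_orientations)
            ]
        )
        for s in range(n_scales)
    ]
    stats["xscl_corr"] = [
        np.array(
            [
                [_norm_corr(mags[s][i], mags[s + 1][j]) for j in range(n_orientations)]
                for i in range(n_orientations)
            ]
        )
        for s in range(n_scales - 1)
    ]
    band_sum = [np.sum(reals[s], axis=0) for s in range(n_scales)]
    stats["band_ac1"] = np.array(
        [_circular_autocorr(band_sum[s], max(1, 2**s)) for s in range(n_scales)]
    )
    stats["band_skew"] = np.array(
        [
            float(sstats.skew(band_sum[s], axis=None))
            if band_sum[s].std() > 1e-12
            else 0.0
            for s in range(n_scales)
        ]
    )
    return stats


# ---------------------------------------------------------------------------
# reduction registry: 32 named features per channel

def _offdiag_mean(m: np.ndarray) -> float:
    k = m.shape[0]
    if k < 2:
        return 0.0
    return float((m.sum() - np.trace(m)) / (k * (k - 1)))


def _reduce_channel(stats: dict, prefix: str) -> dict[str, float]:
    """The 32-feature reduction of one channel's full statistic set.

    Registry (4 scales S, 4 orientations K):
      4  pixel marginals (mean, SD, skew, kurtosis)
      2  lowpass residual skew + kurtosis
      3  lowpass autocorrelation at lags 1..3
      S  per-scale mean subband magnitude (energy spectrum)
      S  per-scale SD of magnitudes across orientations (anisotropy)
      S  per-scale mean within-scale cross-orientation magnitude correlation
      S-1 adjacent-scale mean cross-scale magnitude correlation
      S  per-scale band autocorrelation (scale-matched lag)
      S  per-scale band skewness
    = 4 + 2 + 3 + 4 + 4 + 4 + 3 + 4 + 4 = 32.
    """
    out: dict[str, float] = {}
    px = stats["pixel"]
    out[f"{prefix}_px_mean"] = px["mean"]
    out[f"{prefix}_px_sd"] = px["sd"]
    out[f"{prefix}_px_skew"] = px["skew"]
    out[f"{prefix}_px_kurt"] = px["kurt"]
    out[f"{prefix}_low_skew"] = stats["lowpass"]["skew"]
    out[f"{prefix}_low_kurt"] = stats["lowpass"]["kurt"]
    for i, lag in enumerate((1, 2, 3)):
        out[f"{prefix}_low_ac{lag}"] = float(stats["lowpass_ac"][i])
    mag = stats["mag_means"]
    for s in range(mag.shape[0]):
        out[f"{prefix}_mag_mean_s{s}"] = float(mag[s].mean())
    for s in range(mag.shape[0]):
        out[f"{prefix}_mag_aniso_s{s}"] = float(mag[s].std())
    for s, m in enumerate(stats["xori_corr"]):
        out[f"{prefix}_xori_s{s}"] = _offdiag_mean(m)
    for s, m in enumerate(stats["xscl_corr"]):
        out[f"{prefix}_xscl_s{s}{s+1}"] = float(m.mean())
    for s in range(len(stats["band_ac1"])):
        out[f"{prefix}_band_ac_s{s}"] = float(stats["band_ac1"][s])
    for s in range(len(stats["band_skew"])):
        out[f"{prefix}_band_skew_s{s}"] = float(stats["band_skew"][s])
    return out


def reduce_features(channel_stats: dict[str, dict], variant: str) -> FeatureVector:
    """Reduce per-channel full statistics to one named feature vector.

    ``channel_stats`` maps channel name ("L", "a", "b") to the output of
    :func:`compute_ps_statistics`.  Variants: ``color_means`` (3),
    ``color_stats`` (12), ``ps_gray`` (32, L* only), ``ps_color`` (96),
    ``ps_gray_plus_color`` (union of ps_gray and color_stats; its length is
    logged, not asserted).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {VARIANTS}")
    needed = ("L",) if variant == "ps_gray" else ("L", "a", "b")
    for ch in needed:
        if ch not in channel_stats:
            raise ValueError(f"variant {variant} requires channel {ch!r}")

    def pixel_stats(ch: str) -> dict[str, float]:
        px = channel_stats[ch]["pixel"]
        return {
            f"{ch}_px_mean": px["mean"],
            f"{ch}_px_sd": px["sd"],
            f"{ch}_px_skew": px["skew"],
            f"{ch}_px_kurt": px["kurt"],
        }

    feats: dict[str, float] = {}
    if variant == "color_means":
        for ch in ("L", "a", "b"):
            feats[f"{ch}_px_mean"] = channel_stats[ch]["pixel"]["mean"]
    elif variant == "color_stats":
        for ch in ("L", "a", "b"):
            feats.update(pixel_stats(ch))
    elif variant == "ps_gray":
        feats.update(_reduce_channel(channel_stats["L"], "L"))
    elif variant == "ps_color":
        for ch in ("L", "a", "b"):
            feats.update(_reduce_channel(channel_stats[ch], ch))
    else:  # ps_gray_plus_color
        feats.update(_reduce_channel(channel_stats["L"], "L"))
        for ch in ("a", "b"):
            feats.update(pixel_stats(ch))
        warnings.warn(
            f"ps_gray_plus_color assembled with {len(feats)} features "
            "(union of the grayscale set and the color pixel statistics)",
            stacklevel=2,
        )
    return FeatureVector(
        variant=variant, names=tuple(feats.keys()), values=np.array(list(feats.values()))
    )


def extract_features(
    image: np.ndarray, white_point: np.ndarray, variant: str, crop: int = 128
) -> FeatureVector:
    """Full per-image pipeline: Lab conversion, center crop, statistics."""
    lab = rgb_to_lab(image, white_point)
    channels = ("L",) if variant == "ps_gray" else ("L", "a", "b")
    pixel_only = variant in ("color_means", "color_stats")
    ch_stats = {}
    for ch in channels:
        plane = center_crop(lab.channel(ch), crop)
        if pixel_only:  # the pyramid is not needed for pixel statistics
            ch_stats[ch] = {"pixel": _marginals(plane)}
        else:
            ch_stats[ch] = compute_ps_statistics(plane)
    return reduce_features(ch_stats, variant)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors (same variant) into a DataFrame."""
    if not vectors:
        raise ValueError("no feature vectors supplied")
    variants = {v.variant for v in vectors}
    if len(variants) != 1:
        raise ValueError(f"mixed variants: {variants}")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise ValueError("feature names differ across images")
    return pd.DataFrame([v.values for v in vectors], columns=list(names))


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature across the corpus; constant features dropped."""
    sd = table.std(ddof=0)
    constant = sd[sd < 1e-12].index
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant feature(s): {list(constant)[:5]}...",
            stacklevel=2,
        )
    kept = table.drop(columns=list(constant))
    return (kept - kept.mean()) / kept.std(ddof=0)


def mean_feature_distance(z_rows: pd.DataFrame) -> float:
    """Mean pairwise Euclidean distance over one condition's image set.

    Rows must already be z-scored against the full corpus (zscore_columns),
    so heterogeneous statistics contribute on a common scale.
    """
    x = np.asarray(z_rows, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 images")
    dists = [
        float(np.linalg.norm(x[i] - x[j]))
        for i in range(len(x))
        for j in range(i + 1, len(x))
    ]
    return float(np.mean(dists))


def per_feature_distances(z_rows: pd.DataFrame) -> pd.Series:
    """Mean pairwise absolute difference of each feature over one condition.

    These per-feature distances are the regression predictors: one column
    per feature, so the fit can weight features individually.
    """
    x = np.asarray(z_rows, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 images")
    acc = np.zeros(x.shape[1])
    n_pairs = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            acc += np.abs(x[i] - x[j])
            n_pairs += 1
    return pd.Series(acc / n_pairs, index=z_rows.columns)
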