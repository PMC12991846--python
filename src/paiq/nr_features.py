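"""No-reference natural-scene-statistics features (BRISQUE front end).

Implements MSCN normalization, the four directional pairwise products, and
moment-matched GGD/AGGD fits producing the 36-dimensional BRISQUE feature
vector (18 features at native scale + 18 at 2x downsampled scale).

The final 0-100 BRISQUE score requires a support-vector regressor trained on
human-labeled natural images; that scorer is deliberately not shipped.  The
feature vector is the stable, reproducible part of the chain — plug any
externally trained scorer on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma

from .core import Image

__all__ = [
    "MSCNField",
    "BrisqueFeatures",
    "mscn",
    "pairwise_products",
    "fit_ggd",
    "fit_aggd",
    "brisque_features",
    "FEATURE_NAMES",
]

_SHAPE_GRID = np.arange(0.2, 10.0 + 1e-9, 0.001)
_GGD_RHO = _gamma(2.0 / _SHAPE_GRID) ** 2 / (
    _gamma(1.0 / _SHAPE_GRID) * _gamma(3.0 / _SHAPE_GRID)
)


@dataclass(frozen=True)
class MSCNField:
    coefficients: np.ndarray
    local_mean: np.ndarray
    local_sd: np.ndarray
    C: float


@dataclass(frozen=True)
class BrisqueFeatures:
    vector: np.ndarray  # length 36

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=np.float64)
        if v.shape != (36,):
            raise ValueError(f"BRISQUE feature vector must have length 36, got {v.shape}")
        object.__setattr__(self, "vector", v)


def _gaussian_window(size: int = 7, sigma: float = 7.0 / 6.0) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def mscn(img: Image, window: np.ndarray | None = None, C: float | None = None) -> MSCNField:
    """Mean-subtracted contrast-normalized coefficients.

    I_hat = (I - mu) / (sigma + C) with mu, sigma from Gaussian-weighted
    (7x7, sigma 7/6) local moments; C defaults to data_range / 255.
    """
    w = window if window is not None else _gaussian_window()
    c = C if C is not None else img.data_range / 255.0
    px = img.pixels
    mu = ndimage.convolve(px, w, mode="nearest")
    sigma_sq = ndimage.convolve(px * px, w, mode="nearest") - mu**2
    sigma = np.sqrt(np.maximum(sigma_sq, 0.0))
    return MSCNField(coefficients=(px - mu) / (sigma + c), local_mean=mu, local_sd=sigma, C=c)


def pairwise_products(field: MSCNField) -> dict[str, np.ndarray]:
    """Directional neighbor products H, V, D1, D2 of the MSCN coefficients."""
    f = field.coefficients
    if f.shape[0] < 2 or f.shape[1] < 2:
        raise ValueError("MSCN field must be at least 2x2 for pairwise products")
    return {
        "H": f[:, :-1] * f[:, 1:],
        "V": f[:-1, :] * f[1:, :],
        "D1": f[:-1, :-1] * f[1:, 1:],
        "D2": f[1:, :-1] * f[:-1, 1:],
    }


def _solve_shape(rho: float) -> float:
    """Invert the GGD moment ratio gamma(2/a)^2/(gamma(1/a)gamma(3/a)) = rho."""
    idx = int(np.argmin((_GGD_RHO - rho) ** 2))
    return float(_SHAPE_GRID[idx])


def fit_ggd(samples: np.ndarray) -> tuple[float, float]:
    """Moment-matched generalized Gaussian fit; returns (shape, variance)."""
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 samples for a GGD fit")
    mean_abs = float(np.mean(np.abs(x)))
    var = float(np.mean(x**2))
    if var <= 0.0 or mean_abs <= 0.0:
        raise ValueError("degenerate (all-zero) samples: GGD fit undefined")
    rho = mean_abs**2 / var
    return _solve_shape(rho), var


def fit_aggd(samples: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-matched asymmetric GGD fit.

    Returns (shape, mean, left_variance, right_variance); the mean term is the
    distribution-mean feature eta = (r - l) * Gamma(2/a)/Gamma(1/a) used by
    BRISQUE, where l, r are the left/right scale estimates.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 samples for an AGGD fit")
    left = x[x < 0]
    right = x[x > 0]
    if left.size == 0 or right.size == 0:
        raise ValueError("degenerate one-sided samples: AGGD fit undefined")
    l_sq = float(np.mean(left**2))
    r_sq = float(np.mean(right**2))
    gamma_hat = np.sqrt(l_sq) / np.sqrt(r_sq)
    r_hat = float(np.mean(np.abs(x))) ** 2 / float(np.mean(x**2))
    R_hat = r_hat * (gamma_hat**3 + 1.0) * (gamma_hat + 1.0) / (gamma_hat**2 + 1.0) ** 2
    shape = _solve_shape(R_hat)
    # eta = (b_r - b_l) * Gamma(2/a)/Gamma(1/a), with b = sd * sqrt(G(1/a)/G(3/a))
    const = _gamma(2.0 / shape) / _gamma(1.0 / shape)
    scale_fix = np.sqrt(_gamma(1.0 / shape) / _gamma(3.0 / shape))
    eta = (np.sqrt(r_sq) - np.sqrt(l_sq)) * scale_fix * const
    return shape, float(eta), l_sq, r_sq


_ORIENTS = ("H", "V", "D1", "D2")

FEATURE_NAMES = tuple(
    f"s{scale}_{name}"
    for scale in (1, 2)
    for name in (
        ["ggd_shape", "ggd_var"]
        + [f"{o}_{p}" for o in _ORIENTS for p in ("shape", "mean", "lvar", "rvar")]
    )
)


def _scale_features(img: Image) -> list[float]:
    field = mscn(img)
    feats = list(fit_ggd(field.coefficients))
    for name in _ORIENTS:
        feats.extend(fit_aggd(pairwise_products(field)[name]))
    return feats


def brisque_features(img: Image) -> BrisqueFeatures:
    """The 36-dimensional BRISQUE feature vector (two scales, 18 features each)."""
    if min(img.shape) < 32:
        raise ValueError(f"image {img.id!r} smaller than 32x32: {img.shape}")
    feats = _scale_features(img)
    half = img.pixels[: img.shape[0] - img.shape[0] % 2, : img.shape[1] - img.shape[1] % 2]
    pooled = 0.25 * (half[0::2, 0::2] + half[1::2, 0::2] + half[0::2, 1::2] + half[1::2, 1::2])
    img2 = Image(pooled, data_range=img.data_range, id=f"{img.id}@2x")
    feats.extend(_scale_features(img2))
    return BrisqueFeatures(vector=np.asarray(feats, dtype=np.float64))
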