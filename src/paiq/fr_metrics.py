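"""Full-reference image-quality metrics for photoacoustic reconstructions.

Eleven metrics: PSNR, SSIM, MS-SSIM, IW-SSIM, S3IM (masked SSIM restricted to
structure), HaarPSI, FSIM, GMSD, MS-GMSD, VIF (pixel domain) and UQI.  All of
them operate on a validated :class:`~paiq.core.ImagePair` whose images share a
data range R; constants published for 8-bit (0-255) images are rescaled by
(R/255)^2 so normalized [0, 1] inputs reproduce 8-bit behavior.

GMSD and MS-GMSD are lower-is-better (0 for identical images); every other
metric is higher-is-better with maximum 1 (PSNR: +inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import Image, ImagePair, MetricResult

__all__ = [
    "SSIMConfig",
    "MSSSIMConfig",
    "IWSSIMConfig",
    "S3IMConfig",
    "HaarPSIConfig",
    "FSIMConfig",
    "GMSDConfig",
    "VIFConfig",
    "UQIConfig",
    "FRConfigs",
    "psnr",
    "ssim",
    "ssim_with_map",
    "ms_ssim",
    "iw_ssim",
    "s3im_mask",
    "s3im",
    "haarpsi",
    "fsim",
    "gmsd",
    "ms_gmsd",
    "vif_p",
    "uqi",
    "compute_all_fr",
    "METRIC_ORDER",
    "METRIC_DIRECTIONS",
]

_EPS = 1e-12

# canonical five-scale exponents of multiscale SSIM
_MS_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


# ----------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class SSIMConfig:
    K1: float = 0.01
    K2: float = 0.03
    window_size: int = 11
    window_sigma: float = 1.5

    def __post_init__(self):
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1, K2 must be positive")
        if self.window_size % 2 != 1:
            raise ValueError("window_size must be odd")


@dataclass(frozen=True)
class MSSSIMConfig:
    scales: int = 5
    weights: tuple[float, ...] = _MS_WEIGHTS
    ssim: SSIMConfig = field(default_factory=SSIMConfig)


@dataclass(frozen=True)
class IWSSIMConfig:
    levels: int = 5
    weights: tuple[float, ...] = _MS_WEIGHTS
    neighborhood: int = 3
    sensory_noise_sd: float = 0.03  # relative to data range
    ssim: SSIMConfig = field(default_factory=SSIMConfig)


@dataclass(frozen=True)
class S3IMConfig:
    offset: float = 0.5
    threshold_scale: float = 0.1  # multiplies offset * data_range


@dataclass(frozen=True)
class HaarPSIConfig:
    levels: int = 3
    C: float = 30.0 / 255.0**2  # on data_range 1; rescaled by R^2 internally
    alpha: float = 4.2


@dataclass(frozen=True)
class FSIMConfig:
    n_scales: int = 4
    n_orientations: int = 4
    min_wavelength: float = 6.0
    mult: float = 2.0
    sigma_onf: float = 0.55
    noise_k: float = 2.0
    alpha: float = 1.0
    beta: float = 1.0
    T1: float = 0.85
    T2: float = 160.0 / 255.0**2


@dataclass(frozen=True)
class GMSDConfig:
    c: float = 170.0 / 255.0**2  # 0.0026 on data_range 1
    use_variance: bool = False
    scales: int = 4  # MS-GMSD only
    weights: tuple[float, ...] | None = None  # equal by default


@dataclass(frozen=True)
class VIFConfig:
    sigma_n_sq: float = 2.0  # on the 0-255 scale; rescaled by (R/255)^2
    window_size: int = 9


@dataclass(frozen=True)
class UQIConfig:
    window_size: int = 8
    eps: float = 1e-12


@dataclass(frozen=True)
class FRConfigs:
    """Bundle of per-metric configurations with field-standard defaults."""

    ssim: SSIMConfig = field(default_factory=SSIMConfig)
    ms_ssim: MSSSIMConfig = field(default_factory=MSSSIMConfig)
    iw_ssim: IWSSIMConfig = field(default_factory=IWSSIMConfig)
    s3im: S3IMConfig = field(default_factory=S3IMConfig)
    haarpsi: HaarPSIConfig = field(default_factory=HaarPSIConfig)
    fsim: FSIMConfig = field(default_factory=FSIMConfig)
    gmsd: GMSDConfig = field(default_factory=GMSDConfig)
    vif: VIFConfig = field(default_factory=VIFConfig)
    uqi: UQIConfig = field(default_factory=UQIConfig)


# ----------------------------------------------------------------------------
# windowed-statistics helpers


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _uniform_kernel(size: int) -> np.ndarray:
    return np.full((size, size), 1.0 / size**2)


def _filt_valid(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # kernels are symmetric, so convolution equals correlation
    return signal.fftconvolve(x, kernel, mode="valid")


def _local_moments(x, y, kernel):
    mu_x = _filt_valid(x, kernel)
    mu_y = _filt_valid(y, kernel)
    sig_x = _filt_valid(x * x, kernel) - mu_x**2
    sig_y = _filt_valid(y * y, kernel) - mu_y**2
    sig_xy = _filt_valid(x * y, kernel) - mu_x * mu_y
    return mu_x, mu_y, np.maximum(sig_x, 0.0), np.maximum(sig_y, 0.0), sig_xy


def _mean_pool2(x: np.ndarray) -> np.ndarray:
    """2x2 average pooling with stride 2 (trailing odd row/col dropped)."""
    h, w = x.shape
    x = x[: h - h % 2, : w - w % 2]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def _ssim_maps(x, y, data_range, cfg: SSIMConfig):
    """Return (ssim_map, cs_map, luminance_map) on the valid-window grid."""
    C1 = (cfg.K1 * data_range) ** 2
    C2 = (cfg.K2 * data_range) ** 2
    kernel = _gaussian_kernel(cfg.window_size, cfg.window_sigma)
    mu_x, mu_y, sig_x, sig_y, sig_xy = _local_moments(x, y, kernel)
    lum = (2 * mu_x * mu_y + C1) / (mu_x**2 + mu_y**2 + C1)
    cs = (2 * sig_xy + C2) / (sig_x + sig_y + C2)
    return lum * cs, cs, lum


def _check_window_fits(img_shape, window_size, metric):
    if min(img_shape) < window_size:
        raise ValueError(
            f"{metric}: image {img_shape} smaller than window {window_size}"
        )


# ----------------------------------------------------------------------------
# PSNR


def psnr(pair: ImagePair) -> MetricResult:
    """Peak signal-to-noise ratio, 10*log10(R^2 / MSE), in dB.

    Identical images have MSE 0 and are reported as +inf (not an error).
    """
    diff = pair.reference.pixels - pair.test.pixels
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return MetricResult("PSNR", np.inf, higher_is_better=True)
    value = 10.0 * np.log10(pair.data_range**2 / mse)
    return MetricResult("PSNR", float(value), higher_is_better=True)


# ----------------------------------------------------------------------------
# SSIM family


def ssim_with_map(pair: ImagePair, cfg: SSIMConfig | None = None):
    """Mean SSIM plus the per-window SSIM map (valid-convolution grid)."""
    cfg = cfg or SSIMConfig()
    _check_window_fits(pair.reference.shape, cfg.window_size, "SSIM")
    smap, _, _ = _ssim_maps(
        pair.reference.pixels, pair.test.pixels, pair.data_range, cfg
    )
    return MetricResult("SSIM", float(smap.mean()), True), smap


def ssim(pair: ImagePair, cfg: SSIMConfig | None = None) -> MetricResult:
    """Structural similarity with 11x11 Gaussian (sigma 1.5) local moments."""
    return ssim_with_map(pair, cfg)[0]


def _effective_scales(shape, requested, window_size, metric):
    m = requested
    while m > 1 and min(shape) < 2 ** (m - 1) * window_size:
        m -= 1
    if m < requested:
        warnings.warn(
            f"{metric}: image {shape} too small for {requested} scales; using {m}"
        )
    return m


def ms_ssim(pair: ImagePair, cfg: MSSSIMConfig | None = None) -> MetricResult:
    """Multi-scale SSIM: contrast/structure at every scale, luminance at the coarsest."""
    cfg = cfg or MSSSIMConfig()
    m = _effective_scales(pair.reference.shape, cfg.scales, cfg.ssim.window_size, "MS-SSIM")
    weights = np.asarray(cfg.weights[:m], dtype=np.float64)
    x, y = pair.reference.pixels, pair.test.pixels
    value = 1.0
    for j in range(m):
        smap, cs, _ = _ssim_maps(x, y, pair.data_range, cfg.ssim)
        if j < m - 1:
            value *= max(float(cs.mean()), 0.0) ** weights[j]
            x, y = _mean_pool2(x), _mean_pool2(y)
        else:
            value *= max(float(smap.mean()), 0.0) ** weights[j]
    return MetricResult("MS-SSIM", float(value), True)


def _info_content_weight(ref_band, test_band, cfg: IWSSIMConfig, data_range):
    """Per-pixel information-content weight from a Gaussian scale-mixture view.

    Reference coefficients c with local power s^2 are passed through a gain g
    plus distortion noise v (variance sv^2) to give the test coefficients;
    both percepts see additive sensory noise of variance sigma_n^2.  The
    weight is the mutual information between the source and the two noisy
    percepts, evaluated per location from 3x3 sliding-window moments.
    """
    k = _uniform_kernel(cfg.neighborhood)
    mu_c = _filt_valid(ref_band, k)
    mu_d = _filt_valid(test_band, k)
    s_sq = np.maximum(_filt_valid(ref_band**2, k) - mu_c**2, 0.0)
    d_sq = np.maximum(_filt_valid(test_band**2, k) - mu_d**2, 0.0)
    cov = _filt_valid(ref_band * test_band, k) - mu_c * mu_d
    g = cov / (s_sq + _EPS)
    sv_sq = np.maximum(d_sq - g * cov, 0.0)
    sn_sq = (cfg.sensory_noise_sd * data_range) ** 2
    num = (s_sq + sn_sq) * (g**2 * s_sq + sv_sq + sn_sq) - (g * s_sq) ** 2
    den = sn_sq * (sv_sq + sn_sq)
    return 0.5 * np.log2(np.maximum(num / den, 1.0))


def _center_crop(arr, target_shape):
    dr = arr.shape[0] - target_shape[0]
    dc = arr.shape[1] - target_shape[1]
    r0, c0 = dr // 2, dc // 2
    return arr[r0 : r0 + target_shape[0], c0 : c0 + target_shape[1]]


def iw_ssim(
    pair: ImagePair,
    cfg: IWSSIMConfig | None = None,
    *,
    uniform_weights: bool = False,
) -> MetricResult:
    """Information-content-weighted multiscale SSIM.

    Shares the mean-pool multiscale backbone of :func:`ms_ssim`; the local
    SSIM terms at each scale are averaged with weights proportional to the
    local information content of the bandpass residual at that scale.  With
    ``uniform_weights=True`` the weighting degenerates to the plain mean and
    the score equals MS-SSIM.
    """
    cfg = cfg or IWSSIMConfig()
    m = _effective_scales(pair.reference.shape, cfg.levels, cfg.ssim.window_size, "IW-SSIM")
    weights = np.asarray(cfg.weights[:m], dtype=np.float64)
    x, y = pair.reference.pixels, pair.test.pixels
    value = 1.0
    for j in range(m):
        smap, cs, _ = _ssim_maps(x, y, pair.data_range, cfg.ssim)
        local = smap if j == m - 1 else cs
        if uniform_weights:
            w = np.ones_like(local)
        else:
            if j < m - 1:
                x_lo, y_lo = _mean_pool2(x), _mean_pool2(y)
                band_x = x - _upsample2(x_lo, x.shape)
                band_y = y - _upsample2(y_lo, y.shape)
            else:
                band_x, band_y = x, y
            w_full = _info_content_weight(band_x, band_y, cfg, pair.data_range)
            w = _center_crop(w_full, local.shape) if all(
                a >= b for a, b in zip(w_full.shape, local.shape)
            ) else np.ones_like(local)
            w = np.maximum(w, 0.0) + _EPS
        term = float((w * local).sum() / w.sum())
        if j < m - 1:
            x, y = _mean_pool2(x), _mean_pool2(y)
        value *= max(term, 0.0) ** weights[j]
    return MetricResult("IW-SSIM", float(value), True)


def _upsample2(x: np.ndarray, target_shape) -> np.ndarray:
    out = np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)
    return out[: target_shape[0], : target_shape[1]]


# ----------------------------------------------------------------------------
# S3IM — SSIM restricted to adaptively detected structure


def s3im_neighborhood(height: int) -> int:
    """Neighborhood size of the adaptive threshold: floor(H/16)*2 + 1."""
    n = (height // 16) * 2 + 1
    return max(n, 3)


def s3im_mask(img: Image, cfg: S3IMConfig | None = None) -> np.ndarray:
    """Binary structure mask from Gaussian local thresholding.

    A pixel belongs to the mask iff its intensity exceeds the Gaussian-weighted
    local mean by the margin ``offset * threshold_scale * data_range``; the
    neighborhood size scales with image height.  A constant image therefore
    yields an empty mask (no structure).
    """
    cfg = cfg or S3IMConfig()
    n = s3im_neighborhood(img.shape[0])
    sigma = n / 6.0
    radius = (n - 1) // 2
    local_mean = ndimage.gaussian_filter(
        img.pixels, sigma=sigma, truncate=radius / sigma, mode="nearest"
    )
    margin = cfg.offset * cfg.threshold_scale * img.data_range
    return img.pixels > local_mean + margin


def s3im(
    pair: ImagePair,
    cfg: S3IMConfig | None = None,
    ssim_cfg: SSIMConfig | None = None,
    *,
    mask_override: np.ndarray | None = None,
) -> MetricResult:
    """Sparse SSIM: mean of the SSIM map over the union of structure masks.

    Masks are computed for reference and test, OR-combined, applied
    multiplicatively to both images, and the SSIM map of the masked images is
    averaged over the masked region only.  An empty combined mask (both
    images structureless) returns 1.0 with a warning.
    """
    cfg = cfg or S3IMConfig()
    ssim_cfg = ssim_cfg or SSIMConfig()
    if mask_override is not None:
        mask = mask_override.astype(bool)
    else:
        m1 = s3im_mask(pair.reference, cfg)
        m2 = s3im_mask(pair.test, cfg)
        mask = m1 | m2
    if not mask.any():
        warnings.warn("S3IM: empty structure mask in both images; returning 1.0")
        return MetricResult("S3IM", 1.0, True)
    xm = pair.reference.pixels * mask
    ym = pair.test.pixels * mask
    smap, _, _ = _ssim_maps(xm, ym, pair.data_range, ssim_cfg)
    half = (ssim_cfg.window_size - 1) // 2
    mask_valid = mask[half : mask.shape[0] - half, half : mask.shape[1] - half]
    denom = float(mask_valid.sum())
    if denom == 0.0:
        warnings.warn("S3IM: structure mask lies entirely in the window border; returning 1.0")
        return MetricResult("S3IM", 1.0, True)
    value = float((smap * mask_valid).sum() / denom)
    return MetricResult("S3IM", value, True)


# ----------------------------------------------------------------------------
# HaarPSI


def _haar_filters(level: int) -> tuple[np.ndarray, np.ndarray]:
    n = 2**level
    f = np.full((n, n), 1.0 / n**2)
    f[: n // 2, :] *= -1.0
    return f, f.T  # vertical-edge response, horizontal-edge response


def haarpsi(pair: ImagePair, cfg: HaarPSIConfig | None = None) -> MetricResult:
    """Haar-wavelet perceptual similarity index.

    Both images are 2x mean-pooled, decomposed with three levels of 2D Haar
    high-pass filters in two orientations; local similarities from the two
    finest levels are logistic-mapped and averaged with weights taken from the
    coarsest-level magnitudes, then mapped back and squared.
    """
    cfg = cfg or HaarPSIConfig()
    R = pair.data_range
    C = cfg.C * R**2 / 1.0  # cfg.C already expressed for R=1
    a = cfg.alpha
    x = _mean_pool2(pair.reference.pixels)
    y = _mean_pool2(pair.test.pixels)

    coeffs_x, coeffs_y = [], []
    for lev in range(1, cfg.levels + 1):
        for filt in _haar_filters(lev):
            coeffs_x.append(ndimage.convolve(x, filt, mode="nearest"))
            coeffs_y.append(ndimage.convolve(y, filt, mode="nearest"))
    # layout: [lev1_h, lev1_v, lev2_h, lev2_v, lev3_h, lev3_v]
    sims, weights = [], []
    for orient in range(2):
        mags_x = [np.abs(coeffs_x[2 * lev + orient]) for lev in range(cfg.levels)]
        mags_y = [np.abs(coeffs_y[2 * lev + orient]) for lev in range(cfg.levels)]
        local = sum(
            (2 * mags_x[l] * mags_y[l] + C) / (mags_x[l] ** 2 + mags_y[l] ** 2 + C)
            for l in range(2)
        ) / 2.0
        sims.append(local)
        weights.append(np.maximum(mags_x[cfg.levels - 1], mags_y[cfg.levels - 1]))
    sim = np.concatenate([s.ravel() for s in sims])
    w = np.concatenate([v.ravel() for v in weights])
    logistic = 1.0 / (1.0 + np.exp(-a * sim))
    pooled = float((logistic * w).sum() / (w.sum() + _EPS))
    pooled = min(max(pooled, _EPS), 1.0 - _EPS)
    value = (np.log(pooled / (1.0 - pooled)) / a) ** 2
    return MetricResult("HaarPSI", float(min(value, 1.0)), True)


# ----------------------------------------------------------------------------
# FSIM — phase congruency + gradient magnitude


def _phase_congruency(img: np.ndarray, cfg: FSIMConfig) -> np.ndarray:
    """Kovesi-style phase congruency via a log-Gabor filter bank (FFT domain)."""
    rows, cols = img.shape
    fx = np.fft.fftfreq(cols)
    fy = np.fft.fftfreq(rows)
    u, v = np.meshgrid(fx, fy)
    radius = np.sqrt(u**2 + v**2)
    radius[0, 0] = 1.0
    theta = np.arctan2(-v, u)
    F = np.fft.fft2(img)

    log_gabors = []
    for s in range(cfg.n_scales):
        wavelength = cfg.min_wavelength * cfg.mult**s
        f0 = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(cfg.sigma_onf) ** 2))
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    d_theta_on_sigma = 1.2
    sigma_theta = np.pi / cfg.n_orientations / d_theta_on_sigma
    pc_sum = np.zeros_like(img)
    amp_total = np.zeros_like(img)
    for o in range(cfg.n_orientations):
        angle = o * np.pi / cfg.n_orientations
        ds = np.sin(theta) * np.cos(angle) - np.cos(theta) * np.sin(angle)
        dc = np.cos(theta) * np.cos(angle) + np.sin(theta) * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * sigma_theta**2))

        sum_e = np.zeros_like(img)
        sum_o = np.zeros_like(img)
        sum_amp = np.zeros_like(img)
        eo_list = []
        for s in range(cfg.n_scales):
            eo = np.fft.ifft2(F * log_gabors[s] * spread)
            eo_list.append(eo)
            sum_e += eo.real
            sum_o += eo.imag
            sum_amp += np.abs(eo)
            if s == 0:
                # noise threshold from the finest-scale amplitude distribution
                tau = np.median(np.abs(eo)) / np.sqrt(np.log(4.0))
                em_n = float(np.sum((log_gabors[0] * spread) ** 2)) / (rows * cols)
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + _EPS
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros_like(img)
        for eo in eo_list:
            energy += eo.real * mean_e + eo.imag * mean_o
            energy -= np.abs(eo.real * mean_o - eo.imag * mean_e)
        # expected noise energy over scales (geometric amplitude decay)
        total_tau = tau * (1.0 - (1.0 / cfg.mult) ** cfg.n_scales) / (1.0 - 1.0 / cfg.mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2.0)
        T = noise_mean + cfg.noise_k * noise_sigma
        energy = np.maximum(energy - T, 0.0)
        pc_sum += energy
        amp_total += sum_amp
    return pc_sum / (amp_total + _EPS)


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=np.float64) / 16.0


def _scharr_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(img, _SCHARR_X, mode="nearest")
    gy = ndimage.convolve(img, _SCHARR_X.T, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def fsim(pair: ImagePair, cfg: FSIMConfig | None = None) -> MetricResult:
    """Feature similarity: phase-congruency and gradient similarity, PC-pooled."""
    cfg = cfg or FSIMConfig()
    R = pair.data_range
    x, y = pair.reference.pixels, pair.test.pixels
    pc1 = _phase_congruency(x, cfg)
    pc2 = _phase_congruency(y, cfg)
    g1 = _scharr_magnitude(x)
    g2 = _scharr_magnitude(y)
    T1 = cfg.T1
    T2 = cfg.T2 * R**2
    s_pc = (2 * pc1 * pc2 + T1) / (pc1**2 + pc2**2 + T1)
    s_g = (2 * g1 * g2 + T2) / (g1**2 + g2**2 + T2)
    s_l = (s_pc**cfg.alpha) * (s_g**cfg.beta)
    pcm = np.maximum(pc1, pc2)
    value = float((s_l * pcm).sum() / (pcm.sum() + _EPS))
    return MetricResult("FSIM", value, True)


# ----------------------------------------------------------------------------
# GMSD family


_PREWITT_X = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=np.float64) / 3.0


def _gms_map(x: np.ndarray, y: np.ndarray, c: float) -> np.ndarray:
    """Gradient-magnitude similarity map after the 2x mean prefilter."""
    x = _mean_pool2(x)
    y = _mean_pool2(y)
    gx = np.hypot(
        ndimage.convolve(x, _PREWITT_X, mode="nearest"),
        ndimage.convolve(x, _PREWITT_X.T, mode="nearest"),
    )
    gy = np.hypot(
        ndimage.convolve(y, _PREWITT_X, mode="nearest"),
        ndimage.convolve(y, _PREWITT_X.T, mode="nearest"),
    )
    return (2 * gx * gy + c) / (gx**2 + gy**2 + c)


def gmsd(pair: ImagePair, cfg: GMSDConfig | None = None) -> MetricResult:
    """Gradient-magnitude similarity deviation (lower is better, 0 = identical)."""
    cfg = cfg or GMSDConfig()
    c = cfg.c * pair.data_range**2
    gms = _gms_map(pair.reference.pixels, pair.test.pixels, c)
    spread = float(gms.var()) if cfg.use_variance else float(gms.std())
    return MetricResult("GMSD", spread, higher_is_better=False)


def ms_gmsd(pair: ImagePair, cfg: GMSDConfig | None = None) -> MetricResult:
    """Multi-scale GMSD: weighted RMS of per-scale GMSD over a dyadic pyramid."""
    cfg = cfg or GMSDConfig()
    scales = cfg.scales
    side = min(pair.reference.shape)
    while scales > 1 and side < 2 ** (scales - 1) * 4:
        scales -= 1
    if scales < cfg.scales:
        warnings.warn(f"MS-GMSD: reduced scales to {scales} for image {pair.reference.shape}")
    weights = (
        np.asarray(cfg.weights[:scales], dtype=np.float64)
        if cfg.weights is not None
        else np.full(scales, 1.0 / scales)
    )
    weights = weights / weights.sum()
    x, y = pair.reference.pixels, pair.test.pixels
    vals = []
    for j in range(scales):
        sub = ImagePair(
            reference=Image(x, data_range=pair.data_range, id=pair.reference.id),
            test=Image(y, data_range=pair.data_range, id=pair.test.id),
        ) if min(x.shape) >= 8 else None
        if sub is None:
            break
        vals.append(gmsd(sub, cfg).value)
        x, y = _mean_pool2(x), _mean_pool2(y)
    vals = np.asarray(vals)
    w = weights[: len(vals)] / weights[: len(vals)].sum()
    value = float(np.sqrt((w * vals**2).sum()))
    return MetricResult("MS-GMSD", value, higher_is_better=False)


# ----------------------------------------------------------------------------
# VIF (pixel domain, literal formula) and UQI


def vif_p(pair: ImagePair, cfg: VIFConfig | None = None) -> MetricResult:
    """Pixel-domain visual information fidelity.

    Ratio of the gain-weighted to unweighted local information
    ``sum g * log2(1 + s^2/sn^2) / sum log2(1 + s^2/sn^2)`` where the local
    gain g and reference signal variance s^2 come from sliding-window moments.
    """
    cfg = cfg or VIFConfig()
    R = pair.data_range
    sn_sq = cfg.sigma_n_sq * (R / 255.0) ** 2
    k = _uniform_kernel(cfg.window_size)
    x, y = pair.reference.pixels, pair.test.pixels
    _, _, sig_x, _, sig_xy = _local_moments(x, y, k)
    if float(sig_x.max()) <= 1e-10 * R**2:
        raise ValueError("VIF: reference image is locally constant everywhere")
    g = sig_xy / (sig_x + _EPS)
    info = np.log2(1.0 + sig_x / sn_sq)
    value = float((g * info).sum() / (info.sum() + _EPS))
    return MetricResult("VIF", value, True)


def uqi(pair: ImagePair, cfg: UQIConfig | None = None) -> MetricResult:
    """Universal image quality index over an 8x8 uniform sliding window.

    The epsilon stabilizer in both denominator factors maps fully degenerate
    windows (zero mean and zero variance in both images, e.g. empty
    background) to a contribution of 0 rather than 1, so images dominated by
    exact-zero background score below 1 even against themselves.
    """
    cfg = cfg or UQIConfig()
    _check_window_fits(pair.reference.shape, cfg.window_size, "UQI")
    k = _uniform_kernel(cfg.window_size)
    mu_x, mu_y, sig_x, sig_y, sig_xy = _local_moments(
        pair.reference.pixels, pair.test.pixels, k
    )
    q = (4.0 * mu_x * mu_y * sig_xy) / (
        (mu_x**2 + mu_y**2 + cfg.eps) * (sig_x + sig_y + cfg.eps)
    )
    return MetricResult("UQI", float(q.mean()), True)


# ----------------------------------------------------------------------------
# dispatcher

METRIC_ORDER = (
    "PSNR", "SSIM", "MS-SSIM", "IW-SSIM", "S3IM", "HaarPSI",
    "FSIM", "GMSD", "MS-GMSD", "VIF", "UQI",
)

METRIC_DIRECTIONS = {name: name not in ("GMSD", "MS-GMSD") for name in METRIC_ORDER}


def compute_metrics(
    pair: ImagePair, names: list[str], configs: FRConfigs | None = None
) -> list[MetricResult]:
    """Compute the named full-reference metrics for one pair."""
    cfg = configs or FRConfigs()
    dispatch = {
        "PSNR": lambda: psnr(pair),
        "SSIM": lambda: ssim(pair, cfg.ssim),
        "MS-SSIM": lambda: ms_ssim(pair, cfg.ms_ssim),
        "IW-SSIM": lambda: iw_ssim(pair, cfg.iw_ssim),
        "S3IM": lambda: s3im(pair, cfg.s3im, cfg.ssim),
        "HaarPSI": lambda: haarpsi(pair, cfg.haarpsi),
        "FSIM": lambda: fsim(pair, cfg.fsim),
        "GMSD": lambda: gmsd(pair, cfg.gmsd),
        "MS-GMSD": lambda: ms_gmsd(pair, cfg.gmsd),
        "VIF": lambda: vif_p(pair, cfg.vif),
        "UQI": lambda: uqi(pair, cfg.uqi),
    }
    unknown = set(names) - set(dispatch)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; choose from {METRIC_ORDER}")
    results = []
    for name in names:
        try:
            results.append(dispatch[name]())
        except Exception as exc:
            raise RuntimeError(f"metric {name} failed on pair "
                               f"({pair.reference.id!r}, {pair.test.id!r}): {exc}") from exc
    return results


def compute_all_fr(pair: ImagePair, configs: FRConfigs | None = None) -> list[MetricResult]:
    """All eleven full-reference metrics in canonical order."""
    return compute_metrics(pair, list(METRIC_ORDER), configs)
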