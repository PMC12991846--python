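"""Independent literal re-implementations used as test oracles.

Deliberately naive: explicit window loops and step-by-step formula
evaluation, sharing no code with the package implementation.
"""

import numpy as np


def gaussian_window(size=11, sigma=1.5):
    ax = np.arange(size) - (size - 1) / 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim_windows_loop(x, y, data_range=1.0, size=11, sigma=1.5, K1=0.01, K2=0.03):
    """Per-window SSIM by explicit looping; returns the mean over windows."""
    w = gaussian_window(size, sigma)
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    H, W = x.shape
    vals = []
    for r in range(H - size + 1):
        for c in range(W - size + 1):
            xb = x[r : r + size, c : c + size]
            yb = y[r : r + size, c : c + size]
            mx = (w * xb).sum()
            my = (w * yb).sum()
            vx = (w * xb * xb).sum() - mx**2
            vy = (w * yb * yb).sum() - my**2
            vxy = (w * xb * yb).sum() - mx * my
            vals.append(
                ((2 * mx * my + C1) * (2 * vxy + C2))
                / ((mx**2 + my**2 + C1) * (vx + vy + C2))
            )
    return float(np.mean(vals))


def uqi_windows_loop(x, y, ws=8, eps=1e-12):
    H, W = x.shape
    vals = []
    for r in range(H - ws + 1):
        for c in range(W - ws + 1):
            xb = x[r : r + ws, c : c + ws].ravel()
            yb = y[r : r + ws, c : c + ws].ravel()
            mx, my = xb.mean(), yb.mean()
            vx, vy = xb.var(), yb.var()
            vxy = ((xb - mx) * (yb - my)).mean()
            vals.append(4 * mx * my * vxy / ((mx**2 + my**2 + eps) * (vx + vy + eps)))
    return float(np.mean(vals))


def vif_windows_loop(x, y, ws=9, sigma_n_sq=2.0 / 255.0**2, eps=1e-12):
    H, W = x.shape
    num = den = 0.0
    for r in range(H - ws + 1):
        for c in range(W - ws + 1):
            xb = x[r : r + ws, c : c + ws].ravel()
            yb = y[r : r + ws, c : c + ws].ravel()
            vx = xb.var()
            vxy = ((xb - xb.mean()) * (yb - yb.mean())).mean()
            g = vxy / (vx + eps)
            info = np.log2(1.0 + vx / sigma_n_sq)
            num += g * info
            den += info
    return num / (den + eps)


def meanpool2(x):
    h, w = x.shape
    x = x[: h - h % 2, : w - w % 2]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def prewitt_mag(x):
    kx = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]]) / 3.0
    H, W = x.shape
    xp = np.pad(x, 1, mode="edge")
    gx = np.zeros_like(x)
    gy = np.zeros_like(x)
    for r in range(H):
        for c in range(W):
            block = xp[r : r + 3, c : c + 3]
            gx[r, c] = (block * kx).sum()
            gy[r, c] = (block * kx.T).sum()
    return np.sqrt(gx**2 + gy**2)


def gmsd_literal(x, y, c=170.0 / 255.0**2):
    """GMSD by step-by-step pipeline re-execution (loops for the gradients)."""
    x = meanpool2(x)
    y = meanpool2(y)
    gx = prewitt_mag(x)
    gy = prewitt_mag(y)
    gms = (2 * gx * gy + c) / (gx**2 + gy**2 + c)
    return float(np.sqrt(np.mean((gms - gms.mean()) ** 2)))


def gcnr_histogram(sig, bg, n_bins=100):
    lo = min(sig.min(), bg.min())
    hi = max(sig.max(), bg.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    ps, _ = np.histogram(sig, bins=edges)
    pb, _ = np.histogram(bg, bins=edges)
    return 1.0 - np.minimum(ps / ps.sum(), pb / pb.sum()).sum()


def ggd_samples(shape, variance, n, rng):
    """Draw from a generalized Gaussian via gamma variates.

    If G ~ Gamma(1/a, 1) then b * G^(1/a) with a random sign is GGD(a) with
    scale b; Var = b^2 * Gamma(3/a)/Gamma(1/a).
    """
    from scipy import stats
    from scipy.special import gamma as G

    b = np.sqrt(variance * G(1.0 / shape) / G(3.0 / shape))
    g = stats.gamma(a=1.0 / shape, scale=1.0).rvs(size=n, random_state=rng)
    mags = b * g ** (1.0 / shape)
    signs = rng.choice([-1.0, 1.0], size=n)
    return mags * signs
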