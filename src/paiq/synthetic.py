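"""Synthetic photoacoustic-like phantoms and quality-ordered degradation ladders.

Real photoacoustic reconstructions degrade in two characteristic ways that
this module emulates directly in the image domain:

* **sparse-view streaks** — reconstructing from too few detection angles.
  Emulated by forward-projecting the phantom (Radon transform) over an
  equispaced angle subset and filtered-backprojecting, which produces the
  familiar streak artefacts as the angle count drops;
* **frame-averaging noise** — additive Gaussian noise whose standard
  deviation falls as 1/sqrt(n_frames), emulating electronic noise averaged
  over repeated acquisitions.

An SNR-ladder family (noise set by a target dB level) and one domain-shifted
configuration (multiplicative speckle plus blur, used for out-of-distribution
tests) complete the picture.  Full wave propagation and beamforming physics
are out of scope; only the image-domain signature of the degradations is
reproduced.

Everything is deterministic: a single global seed fans out to per-image and
per-level streams via ``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import iradon, radon

from .core import Image, LadderManifest, LadderSubset, save_image, write_manifest

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "generate_phantom",
    "degrade_sparse_view",
    "degrade_frame_averaging",
    "degrade_snr",
    "degrade_domain_shift",
    "build_ladder",
    "build_benchmark_suite",
    "SPARSE_VIEW_LEVELS",
    "FRAME_LEVELS",
    "SNR_DB_LEVELS",
]

SPARSE_VIEW_LEVELS = (8, 16, 32, 64, 128)
FRAME_LEVELS = (128, 256, 384, 640, 1280, 2560)
SNR_DB_LEVELS = (10, 20, 30, 40, 50)

#: per-frame noise standard deviation for the frame-averaging family; after
#: averaging the ladder spans sd 0.18 (128 frames) down to 0.04 (2560 frames)
#: on [0, 1] images, a realistic span for normalized reconstructions
DEFAULT_SIGMA0 = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "vessel"  # "vessel" | "derenzo"
    size: int = 128
    n_branches: int = 6
    n_sectors: int = 6
    discs_per_sector: int = 3
    intensity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("vessel", "derenzo"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not (0.0 < self.intensity <= 1.0):
            raise ValueError("intensity must lie in (0, 1]")


@dataclass(frozen=True)
class DegradationSpec:
    family: str  # "sparse_view" | "frame_averaging" | "snr_db" | "domain_shift"
    levels: tuple = SPARSE_VIEW_LEVELS
    sigma0: float = DEFAULT_SIGMA0
    seed: int = 0

    def __post_init__(self):
        known = ("sparse_view", "frame_averaging", "snr_db", "domain_shift")
        if self.family not in known:
            raise ValueError(f"unknown degradation family {self.family!r}")
        lv = tuple(self.levels)
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing (higher = better quality)")
        object.__setattr__(self, "levels", lv)


# ----------------------------------------------------------------------------
# phantoms


def _stamp_disk(canvas: np.ndarray, r: float, c: float, radius: float, value: float):
    rr, cc = np.ogrid[: canvas.shape[0], : canvas.shape[1]]
    mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    canvas[mask] = np.maximum(canvas[mask], value)


def _vessel_phantom(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size
    canvas = np.zeros((n, n))
    target_lo = 0.02 * n * n
    target_hi = 0.25 * n * n
    branches = 0
    # grow smooth random-walk vessels until the foreground is in range
    while branches < spec.n_branches or (canvas > 0).sum() < target_lo:
        r = rng.uniform(0.1 * n, 0.9 * n)
        c = rng.uniform(0.1 * n, 0.9 * n)
        heading = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(0.5, 2.0)  # radius -> stroke width 1-4 px
        steps = int(rng.integers(n // 2, int(1.2 * n)))
        amplitude = rng.uniform(0.6, 1.0)
        for _ in range(steps):
            _stamp_disk(canvas, r, c, width, amplitude)
            heading += rng.normal(0.0, 0.25)
            r += np.sin(heading)
            c += np.cos(heading)
            if not (1 <= r < n - 1 and 1 <= c < n - 1):
                break
        branches += 1
        if (canvas > 0).sum() > target_hi * 0.8 or branches > 4 * spec.n_branches:
            break
    canvas = ndimage.gaussian_filter(canvas, 0.8)
    if canvas.max() > 0:
        canvas /= canvas.max()
    return canvas * spec.intensity


def _derenzo_phantom(spec: PhantomSpec) -> np.ndarray:
    n = spec.size
    canvas = np.zeros((n, n))
    center = (n - 1) / 2.0
    ring_r = 0.30 * n
    max_radius = 0.045 * n
    placed: list[tuple[float, float, float]] = []
    for s in range(spec.n_sectors):
        angle = 2 * np.pi * s / spec.n_sectors
        radius = max_radius * (1.0 - 0.6 * s / max(spec.n_sectors - 1, 1))
        radius = max(radius, 1.5)
        anchor_r = center + ring_r * np.sin(angle)
        anchor_c = center + ring_r * np.cos(angle)
        # discs of a sector sit on a small triangle around the anchor; the
        # separation is grown until no placed disc is touched, so the
        # connected-component count always equals the disc count
        for t in range(spec.discs_per_sector):
            phi = angle + 2 * np.pi * t / spec.discs_per_sector
            sep = 1.6 * radius + 2.5
            while True:
                rr = anchor_r + sep * np.sin(phi)
                cc = anchor_c + sep * np.cos(phi)
                rr = float(np.clip(rr, radius + 1, n - radius - 2))
                cc = float(np.clip(cc, radius + 1, n - radius - 2))
                ok = all(
                    np.hypot(rr - pr, cc - pc) >= radius + prad + 2.0
                    for pr, pc, prad in placed
                )
                if ok or sep > n:
                    break
                sep += 1.0
            placed.append((rr, cc, radius))
            _stamp_disk(canvas, rr, cc, radius, 1.0)
    canvas = ndimage.gaussian_filter(canvas, 0.6)
    if canvas.max() > 0:
        canvas /= canvas.max()
    return canvas * spec.intensity


def generate_phantom(spec: PhantomSpec) -> Image:
    """Deterministic phantom image for the given spec (same spec => same pixels)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.kind == "vessel":
        px = _vessel_phantom(spec, rng)
    else:
        px = _derenzo_phantom(spec)
    return Image(px, data_range=1.0, id=f"{spec.kind}-{spec.seed}")


# ----------------------------------------------------------------------------
# degradations


def _renorm(px: np.ndarray) -> np.ndarray:
    px = np.clip(px, 0.0, None)
    mx = px.max()
    return px / mx if mx > 0 else px


def degrade_sparse_view(img: Image, n_angles: int, *, _sinogram_cache=None) -> Image:
    """Filtered backprojection from *n_angles* equispaced view angles in [0, 180).

    Deterministic given (img, n_angles).  Fewer angles produce the
    characteristic streak artefacts of angularly undersampled tomography.
    """
    if n_angles < 4:
        raise ValueError("need at least 4 view angles")
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    if _sinogram_cache is not None:
        dense_theta, dense_sino = _sinogram_cache
        stride = len(dense_theta) // n_angles
        if stride * n_angles == len(dense_theta) and np.allclose(
            dense_theta[::stride], theta
        ):
            sino = dense_sino[:, ::stride]
        else:
            sino = radon(img.pixels, theta=theta, circle=False)
    else:
        sino = radon(img.pixels, theta=theta, circle=False)
    recon = iradon(
        sino, theta=theta, circle=False, filter_name="ramp",
        output_size=max(img.shape),
    )
    recon = recon[: img.shape[0], : img.shape[1]]
    return Image(_renorm(recon), data_range=1.0, id=f"{img.id}-sv{n_angles}")


def degrade_frame_averaging(
    img: Image, n_frames: int, sigma0: float = DEFAULT_SIGMA0, seed=0
) -> Image:
    """Additive Gaussian noise of sd sigma0/sqrt(n_frames), clipped to [0, 1]."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    rng = np.random.default_rng(seed)
    noisy = img.pixels + rng.normal(0.0, sigma0 / np.sqrt(n_frames), img.shape)
    return Image(
        np.clip(noisy, 0.0, 1.0), data_range=1.0, id=f"{img.id}-fa{n_frames}"
    )


def degrade_snr(img: Image, snr_db: float, seed=0) -> Image:
    """Additive Gaussian noise scaled so the RMS-signal-to-noise ratio is snr_db."""
    rng = np.random.default_rng(seed)
    rms = float(np.sqrt(np.mean(img.pixels**2)))
    sd = rms / 10.0 ** (snr_db / 20.0)
    noisy = img.pixels + rng.normal(0.0, sd, img.shape)
    return Image(np.clip(noisy, 0.0, 1.0), data_range=1.0, id=f"{img.id}-snr{snr_db:g}")


def degrade_domain_shift(img: Image, level: float, seed=0) -> Image:
    """Out-of-distribution degradation: 2-px blur plus multiplicative speckle.

    ``level`` is a quality index; speckle strength is 0.8/level so larger
    levels mean higher quality, matching the ladder convention.
    """
    rng = np.random.default_rng(seed)
    blurred = ndimage.gaussian_filter(img.pixels, 2.0)
    strength = 0.8 / max(float(level), 1e-6)
    speckled = blurred * (1.0 + strength * rng.normal(0.0, 1.0, img.shape))
    speckled += 0.05 * strength * rng.normal(0.0, 1.0, img.shape)
    return Image(
        _renorm(speckled), data_range=1.0, id=f"{img.id}-ds{level:g}"
    )


def _degrade(img: Image, deg: DegradationSpec, level, seed) -> Image:
    if deg.family == "sparse_view":
        return degrade_sparse_view(img, int(level))
    if deg.family == "frame_averaging":
        return degrade_frame_averaging(img, int(level), deg.sigma0, seed)
    if deg.family == "snr_db":
        return degrade_snr(img, float(level), seed)
    return degrade_domain_shift(img, float(level), seed)


def _child_seed(root: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(root, spawn_key=key)


# ----------------------------------------------------------------------------
# ladders


def build_ladder(
    spec: PhantomSpec,
    deg: DegradationSpec,
    n_images: int,
    out_dir,
    dataset: str | None = None,
) -> LadderManifest:
    """Generate a quality ladder on disk and return its manifest.

    ``n_images`` distinct phantoms (seed-derived) are each degraded at every
    level of ``deg``; the clean phantom is stored as the reference of its own
    degraded versions.  Subset quality_rank is the level index.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images per level")
    out_dir = Path(out_dir)
    dataset = dataset or f"{spec.kind}_{deg.family}"
    img_dir = out_dir / dataset
    img_dir.mkdir(parents=True, exist_ok=True)

    references = []
    sinograms = []
    dense_angles = max(deg.levels) if deg.family == "sparse_view" else None
    for i in range(n_images):
        pspec = PhantomSpec(
            kind=spec.kind, size=spec.size, n_branches=spec.n_branches,
            n_sectors=spec.n_sectors, discs_per_sector=spec.discs_per_sector,
            intensity=spec.intensity,
            seed=int(np.random.default_rng(_child_seed(spec.seed, i)).integers(2**31 - 1)),
        )
        ref = generate_phantom(pspec)
        ref_path = img_dir / f"ref_{i:03d}.png"
        save_image(ref, ref_path)
        references.append((ref, str(ref_path)))
        if dense_angles is not None:
            theta = np.linspace(0.0, 180.0, dense_angles, endpoint=False)
            sinograms.append((theta, radon(ref.pixels, theta=theta, circle=False)))

    subsets = []
    for li, level in enumerate(deg.levels):
        records = []
        for i, (ref, ref_path) in enumerate(references):
            seed = _child_seed(deg.seed, li, i)
            if deg.family == "sparse_view":
                test = degrade_sparse_view(ref, int(level), _sinogram_cache=sinograms[i])
            else:
                test = _degrade(ref, deg, level, seed)
            test_path = img_dir / f"lvl{li}_{level}_{i:03d}.png"
            save_image(test, test_path)
            records.append((str(test_path), ref_path))
        subsets.append(
            LadderSubset(label=f"{deg.family}_{level}", quality_rank=li, records=tuple(records))
        )
    manifest = LadderManifest(dataset=dataset, subsets=tuple(subsets))
    write_manifest(manifest, out_dir / f"{dataset}_manifest.csv")
    return manifest


def build_benchmark_suite(
    seed: int, out_dir, n_images: int = 8, size: int = 128
) -> dict[str, LadderManifest]:
    """The four-ladder benchmark suite used throughout tests and examples.

    Three in-distribution ladders (vessel/sparse-view, vessel/frame-averaging,
    derenzo/sparse-view) plus one domain-shifted ladder (derenzo with speckle
    and blur) playing the out-of-distribution role.
    """
    out_dir = Path(out_dir)
    suite = {}
    vessel = PhantomSpec(kind="vessel", size=size, seed=seed)
    vessel2 = PhantomSpec(kind="vessel", size=size, seed=seed + 1)
    derenzo = PhantomSpec(kind="derenzo", size=size, seed=seed + 2)
    derenzo2 = PhantomSpec(kind="derenzo", size=size, seed=seed + 3)
    configs = [
        ("vessel_sparse", vessel, DegradationSpec("sparse_view", SPARSE_VIEW_LEVELS, seed=seed)),
        ("vessel_frames", vessel2, DegradationSpec("frame_averaging", FRAME_LEVELS, seed=seed + 1)),
        ("derenzo_sparse", derenzo, DegradationSpec("sparse_view", SPARSE_VIEW_LEVELS, seed=seed + 2)),
        ("shifted_derenzo", derenzo2, DegradationSpec("domain_shift", (1.0, 2.0, 4.0, 8.0), seed=seed + 3)),
    ]
    for name, pspec, dspec in configs:
        suite[name] = build_ladder(pspec, dspec, n_images, out_dir, dataset=name)
    return suite
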