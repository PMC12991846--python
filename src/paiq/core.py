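"""Core data model shared by every other module.

Images are 2D float grids with an explicit ``data_range`` (the maximum
possible pixel value, 1.0 after normalization).  Geometry is 0-based,
row-major, half-open, origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Image",
    "ImagePair",
    "ROI",
    "ROIPairSet",
    "LadderSubset",
    "LadderManifest",
    "MetricResult",
    "FormatError",
    "GeometryError",
    "PairingError",
    "ManifestError",
    "load_image",
    "save_image",
    "normalize_minmax",
    "crop_region",
    "validate_pair",
    "read_manifest",
    "write_manifest",
    "read_roi_file",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["dataset", "subset", "quality_rank", "path_test", "path_reference"]


class FormatError(ValueError):
    """Unsupported or malformed image data."""


class GeometryError(ValueError):
    """ROI geometry outside the image or otherwise invalid."""


class PairingError(ValueError):
    """Reference/test images cannot form a full-reference pair."""


class ManifestError(ValueError):
    """Malformed quality-ladder manifest."""


@dataclass(frozen=True)
class Image:
    """A single 2D grayscale reconstruction.

    Parameters
    ----------
    pixels
        2D float array (rows x cols); finite values only.
    data_range
        Maximum possible pixel value R (1.0 after min-max normalization).
    id
        Free-form label used in error messages and result tables.
    """

    pixels: np.ndarray
    data_range: float = 1.0
    id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise FormatError(f"image {self.id!r}: expected 2D grid, got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise FormatError(f"image {self.id!r}: minimum size is 8x8, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise FormatError(f"image {self.id!r}: non-finite pixel values")
        if not (self.data_range > 0):
            raise FormatError(f"image {self.id!r}: data_range must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ImagePair:
    """A (reference, test) image pair — the unit of full-reference scoring."""

    reference: Image
    test: Image

    @property
    def data_range(self) -> float:
        return self.reference.data_range


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle, half-open extent [row0, row0+height) x [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int
    kind: str = "signal"  # "signal" | "background"

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise GeometryError(f"ROI with non-positive extent: {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise GeometryError(f"ROI with negative origin: {self}")
        if self.kind not in ("signal", "background"):
            raise GeometryError(f"ROI kind must be 'signal' or 'background', got {self.kind!r}")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class ROIPairSet:
    """Signal/background ROI pairings for one image (three pairs by convention)."""

    pairs: tuple[tuple[ROI, ROI], ...]

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise GeometryError("ROIPairSet needs at least one (signal, background) pair")
        for i, (sig, bg) in enumerate(self.pairs):
            if (sig.height, sig.width) != (bg.height, bg.width):
                raise GeometryError(
                    f"pair {i}: signal and background ROIs must have identical size, "
                    f"got {(sig.height, sig.width)} vs {(bg.height, bg.width)}"
                )


@dataclass(frozen=True)
class LadderSubset:
    label: str
    quality_rank: int
    records: tuple[tuple[str, str], ...]  # (path_test, path_reference)


@dataclass(frozen=True)
class LadderManifest:
    """A dataset's subsets ordered by expected quality (low to high)."""

    dataset: str
    subsets: tuple[LadderSubset, ...]

    def __post_init__(self):
        ranks = [s.quality_rank for s in self.subsets]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ManifestError(f"quality ranks not strictly increasing: {ranks}")

    @property
    def n_images(self) -> int:
        return sum(len(s.records) for s in self.subsets)


@dataclass(frozen=True)
class MetricResult:
    metric: str
    value: float
    higher_is_better: bool = True


# ----------------------------------------------------------------------------
# image I/O


def load_image(path, data_range_hint: float | None = None, id: str | None = None) -> Image:
    """Load a PNG/TIFF/NPY image as a 2D :class:`Image`.

    Integer formats are divided by their bit-depth maximum so the result lives
    in [0, 1] with data_range 1.0; float inputs are kept as-is with the
    supplied (or inferred max-value) data_range.
    """
    path = Path(path)
    if id is None:
        id = path.stem
    try:
        if path.suffix.lower() == ".npy":
            arr = np.load(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.squeeze(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        # grayscale stored as RGB(A): channels are identical by contract
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2D grayscale data, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        maxval = float(np.iinfo(arr.dtype).max)
        return Image(arr.astype(np.float64) / maxval, data_range=1.0, id=id)
    arr = arr.astype(np.float64)
    if data_range_hint is not None:
        rng = float(data_range_hint)
    else:
        rng = float(arr.max()) if arr.size and arr.max() > 0 else 1.0
    return Image(arr, data_range=rng, id=id)


def save_image(img: Image, path) -> None:
    """Write as 16-bit PNG (values scaled by data_range) or .npy float dump."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".npy":
        np.save(path, img.pixels)
        return
    scaled = np.clip(img.pixels / img.data_range, 0.0, 1.0)
    iio.imwrite(path, np.round(scaled * 65535).astype(np.uint16))


# ----------------------------------------------------------------------------
# elementary transforms


def normalize_minmax(img: Image) -> Image:
    """Per-image min-max normalization to [0, 1] (data_range becomes 1.0).

    A constant image maps to all-zeros by convention so fully degraded
    background-only frames still flow through batch pipelines.
    """
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi - lo == 0.0:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return Image(out, data_range=1.0, id=img.id)


def crop_region(img: Image, roi: ROI) -> Image:
    """Extract the half-open sub-grid addressed by *roi*."""
    rows, cols = img.shape
    if roi.row0 + roi.height > rows or roi.col0 + roi.width > cols:
        raise GeometryError(
            f"ROI {roi} exceeds image {img.id!r} of shape {img.shape}"
        )
    sub = img.pixels[roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width]
    return Image(sub.copy(), data_range=img.data_range, id=f"{img.id}[{roi.row0}:{roi.col0}]") \
        if min(sub.shape) >= 8 else _small_image(sub, img)


def _small_image(sub: np.ndarray, parent: Image) -> "Image":
    # Image enforces >= 8x8 for full frames; ROI crops may legitimately be
    # smaller, so bypass the size check while keeping the other invariants.
    img = object.__new__(Image)
    object.__setattr__(img, "pixels", np.asarray(sub, dtype=np.float64).copy())
    object.__setattr__(img, "data_range", parent.data_range)
    object.__setattr__(img, "id", f"{parent.id}[crop]")
    return img


def crop_pixels(img: Image, roi: ROI) -> np.ndarray:
    """Like :func:`crop_region` but returns the raw array view."""
    rows, cols = img.shape
    if roi.row0 + roi.height > rows or roi.col0 + roi.width > cols:
        raise GeometryError(f"ROI {roi} exceeds image {img.id!r} of shape {img.shape}")
    return img.pixels[roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width]


def validate_pair(reference: Image, test: Image) -> ImagePair:
    """Enforce identical shape and data_range; return the validated pair."""
    if reference.shape != test.shape:
        raise PairingError(
            f"shape mismatch: {reference.id!r} {reference.shape} vs {test.id!r} {test.shape}"
        )
    if not np.isclose(reference.data_range, test.data_range):
        raise PairingError(
            f"data_range mismatch: {reference.id!r} {reference.data_range} "
            f"vs {test.id!r} {test.data_range}"
        )
    return ImagePair(reference=reference, test=test)


# ----------------------------------------------------------------------------
# manifests


def read_manifest(path, check_files: bool = True) -> LadderManifest:
    """Read a quality-ladder manifest CSV.

    Expected header: ``dataset,subset,quality_rank,path_test,path_reference``.
    Rows may appear in any order; subsets are sorted by quality_rank.
    Relative paths resolve against the manifest's directory; with
    ``check_files`` every referenced file must exist.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    try:
        ranks = df["quality_rank"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ManifestError(f"{path}: non-integer quality_rank") from exc
    df = df.assign(quality_rank=ranks)
    if df.duplicated(subset=["subset", "path_test"]).any():
        dup = df[df.duplicated(subset=["subset", "path_test"])].iloc[0]
        raise ManifestError(f"{path}: duplicate record {dup['subset']}/{dup['path_test']}")
    rank_map = df.groupby("subset")["quality_rank"].nunique()
    if (rank_map > 1).any():
        raise ManifestError(f"{path}: subset with inconsistent quality_rank")
    per_rank = df.groupby("quality_rank")["subset"].nunique()
    if (per_rank > 1).any():
        raise ManifestError(f"{path}: distinct subsets share a quality_rank")
    datasets = df["dataset"].unique()
    if len(datasets) != 1:
        raise ManifestError(f"{path}: expected a single dataset per manifest, got {list(datasets)}")

    base = Path(path).parent
    subsets = []
    for (rank, label), grp in sorted(
        df.groupby(["quality_rank", "subset"]), key=lambda kv: kv[0][0]
    ):
        records = tuple(
            (_resolve(base, r.path_test), _resolve(base, r.path_reference))
            for r in grp.itertuples()
        )
        if check_files:
            for rec in records:
                for p in rec:
                    if not Path(p).exists():
                        raise ManifestError(f"{path}: referenced file missing: {p}")
        subsets.append(LadderSubset(label=str(label), quality_rank=int(rank), records=records))
    return LadderManifest(dataset=str(datasets[0]), subsets=tuple(subsets))


def _resolve(base: Path, p: str) -> str:
    q = Path(p)
    return str(q if q.is_absolute() else base / q)


def write_manifest(manifest: LadderManifest, path) -> None:
    rows = []
    for sub in manifest.subsets:
        for test_path, ref_path in sub.records:
            rows.append(
                {
                    "dataset": manifest.dataset,
                    "subset": sub.label,
                    "quality_rank": sub.quality_rank,
                    "path_test": test_path,
                    "path_reference": ref_path,
                }
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_roi_file(path) -> dict[str, ROIPairSet]:
    """Read ROI definitions keyed by image_id.

    CSV columns: ``image_id,pair_index,kind,row0,col0,height,width``.
    """
    df = pd.read_csv(path)
    needed = ["image_id", "pair_index", "kind", "row0", "col0", "height", "width"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing ROI columns {missing}")
    out: dict[str, ROIPairSet] = {}
    for image_id, grp in df.groupby("image_id"):
        pairs = []
        for pair_index, pg in sorted(grp.groupby("pair_index"), key=lambda kv: kv[0]):
            kinds = dict()
            for r in pg.itertuples():
                kinds[r.kind] = ROI(
                    row0=int(r.row0), col0=int(r.col0),
                    height=int(r.height), width=int(r.width), kind=str(r.kind),
                )
            if set(kinds) != {"signal", "background"}:
                raise ManifestError(
                    f"{path}: image {image_id!r} pair {pair_index} needs exactly one "
                    f"signal and one background ROI"
                )
            pairs.append((kinds["signal"], kinds["background"]))
        out[str(image_id)] = ROIPairSet(pairs=tuple(pairs))
    return out
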