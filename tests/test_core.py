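import numpy as np
import pytest

from paiq.core import (
    FormatError,
    GeometryError,
    Image,
    LadderManifest,
    LadderSubset,
    ManifestError,
    PairingError,
    ROI,
    ROIPairSet,
    crop_region,
    load_image,
    normalize_minmax,
    read_manifest,
    save_image,
    validate_pair,
    write_manifest,
)


class TestImage:
    def test_rejects_non_finite(self):
        px = np.ones((16, 16))
        px[3, 3] = np.nan
        with pytest.raises(FormatError):
            Image(px)

    def test_rejects_tiny_and_wrong_ndim(self):
        with pytest.raises(FormatError):
            Image(np.ones((4, 4)))
        with pytest.raises(FormatError):
            Image(np.ones((8, 8, 3)))


class TestLoadSave:
    def test_uint16_png_roundtrip(self, tmp_path, rng):
        px = rng.random((32, 32))
        save_image(Image(px), tmp_path / "a.png")
        loaded = load_image(tmp_path / "a.png")
        assert loaded.data_range == 1.0
        assert np.allclose(loaded.pixels, px, atol=1.0 / 65535)

    def test_uint8_scaled_by_bit_depth(self, tmp_path):
        import imageio.v3 as iio

        arr = np.zeros((16, 16), dtype=np.uint8)
        arr[0, 0] = 255
        iio.imwrite(tmp_path / "b.png", arr)
        img = load_image(tmp_path / "b.png")
        assert img.pixels.max() == 1.0 and img.pixels.min() == 0.0

    def test_all_zero_tiff(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "z.tif", np.zeros((16, 16), dtype=np.uint16))
        img = load_image(tmp_path / "z.tif")
        assert np.all(img.pixels == 0.0)

    def test_float_npy_keeps_values_with_hint(self, tmp_path, rng):
        px = rng.random((16, 16)) * 7.3
        np.save(tmp_path / "f.npy", px)
        img = load_image(tmp_path / "f.npy", data_range_hint=7.3)
        assert img.data_range == 7.3
        assert np.array_equal(img.pixels, px)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_image(tmp_path / "nope.png")


class TestNormalize:
    def test_affine_map(self):
        img = Image(np.tile([[0.0, 2.0], [4.0, 8.0]], (4, 4)))
        out = normalize_minmax(img)
        assert np.array_equal(
            out.pixels, np.tile([[0.0, 0.25], [0.5, 1.0]], (4, 4))
        )

    def test_constant_maps_to_zeros(self):
        out = normalize_minmax(Image(np.full((16, 16), 5.0), data_range=10.0))
        assert np.all(out.pixels == 0.0)
        assert out.data_range == 1.0

    def test_idempotent(self, rng):
        img = Image(rng.random((32, 32)) * 3.0, data_range=3.0)
        once = normalize_minmax(img)
        twice = normalize_minmax(once)
        assert np.array_equal(once.pixels, twice.pixels)
        assert once.pixels.min() == 0.0 and once.pixels.max() == 1.0


class TestCropAndPairs:
    def test_full_image_crop_is_identity(self, rng):
        img = Image(rng.random((32, 48)))
        out = crop_region(img, ROI(0, 0, 32, 48))
        assert np.array_equal(out.pixels, img.pixels)

    def test_out_of_bounds(self, rng):
        img = Image(rng.random((128, 128)))
        with pytest.raises(GeometryError):
            crop_region(img, ROI(120, 120, 16, 16))

    def test_top_left_block(self, rng):
        img = Image(rng.random((128, 128)))
        out = crop_region(img, ROI(0, 0, 64, 64))
        assert np.array_equal(out.pixels, img.pixels[:64, :64])

    def test_pair_validation(self, rng):
        a = Image(rng.random((32, 32)), id="a")
        b = Image(rng.random((32, 32)), id="b")
        assert validate_pair(a, b).reference is a
        with pytest.raises(PairingError, match="shape"):
            validate_pair(a, Image(rng.random((64, 64))))
        with pytest.raises(PairingError, match="data_range"):
            validate_pair(a, Image(rng.random((32, 32)) * 255, data_range=255.0))

    def test_roi_pair_set_requires_equal_sizes(self):
        with pytest.raises(GeometryError):
            ROIPairSet(pairs=((ROI(0, 0, 4, 4), ROI(0, 0, 4, 8)),))


class TestManifest:
    def _manifest(self, tmp_path):
        names = ["low_0.png", "low_1.png", "high_0.png", "high_1.png",
                 "ref_0.png", "ref_1.png"]
        for name in names:
            save_image(Image(np.zeros((8, 8))), tmp_path / name)
        subsets = (
            LadderSubset("low", 0, (("low_0.png", "ref_0.png"), ("low_1.png", "ref_1.png"))),
            LadderSubset("high", 1, (("high_0.png", "ref_0.png"), ("high_1.png", "ref_1.png"))),
        )
        return LadderManifest(dataset="demo", subsets=subsets)

    def test_roundtrip_and_row_order_independence(self, tmp_path):
        m = self._manifest(tmp_path)
        write_manifest(m, tmp_path / "m.csv")
        back = read_manifest(tmp_path / "m.csv")
        assert back.dataset == "demo"
        assert [s.label for s in back.subsets] == ["low", "high"]
        assert back.n_images == 4

        # shuffling rows leaves the parsed manifest unchanged
        import pandas as pd

        df = pd.read_csv(tmp_path / "m.csv")
        df.sample(frac=1, random_state=0).to_csv(tmp_path / "shuffled.csv", index=False)
        shuffled = read_manifest(tmp_path / "shuffled.csv")
        assert [s.label for s in shuffled.subsets] == [s.label for s in back.subsets]
        assert {r for s in shuffled.subsets for r in s.records} == {
            r for s in back.subsets for r in s.records
        }

    @pytest.mark.parametrize(
        "mutation, message",
        [
            (lambda df: df.drop(columns=["quality_rank"]), "missing"),
            (lambda df: df.assign(quality_rank="x"), "non-integer"),
            (lambda df: df.assign(quality_rank=1), "share"),
            (lambda df: df.iloc[[0, 0, 1, 2, 3]], "duplicate"),
        ],
    )
    def test_malformed_manifests(self, tmp_path, mutation, message):
        import pandas as pd

        write_manifest(self._manifest(tmp_path), tmp_path / "m.csv")
        df = mutation(pd.read_csv(tmp_path / "m.csv"))
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ManifestError, match=message):
            read_manifest(tmp_path / "bad.csv")

    def test_rank_order_enforced(self):
        with pytest.raises(ManifestError):
            LadderManifest(
                dataset="d",
                subsets=(
                    LadderSubset("a", 1, (("t", "r"),)),
                    LadderSubset("b", 1, (("t2", "r"),)),
                ),
            )
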