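"""Synthetic scene generation and anomaly injection."""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest
from scipy import ndimage

from autoqc.io_datasets import read_manifest
from autoqc.synthetic_data import (
    ANOMALY_KINDS,
    AnomalySpec,
    SceneSpec,
    generate_normal,
    inject_anomaly,
    make_benchmark,
)

LOCALIZED = ("air_bubble", "artifact", "contamination")
WHOLE_FRAME = ("z_shift", "illumination")


class TestGenerateNormal:
    def test_empty_noiseless_scene_is_constant_background(self):
        spec = SceneSpec(cell_count=0, noise_sigma=0.0, background_level=0.6)
        img = generate_normal(spec)
        assert np.all(img.pixels == 0.6)

    def test_seeded_determinism(self):
        spec = SceneSpec(seed=42)
        a = generate_normal(spec)
        b = generate_normal(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_cell_count_matches_connected_components(self):
        spec = SceneSpec(height=128, width=128, cell_count=10, seed=7)
        img = generate_normal(spec)
        thr = spec.background_level - spec.cell_darkness / 2
        labels, n = ndimage.label(img.pixels < thr)
        assert n == 10

    def test_polarity_inversion(self):
        bright = generate_normal(SceneSpec(seed=3, noise_sigma=0.0))
        dark = generate_normal(SceneSpec(seed=3, noise_sigma=0.0, polarity="dark"))
        assert np.allclose(bright.pixels + dark.pixels, 1.0)

    def test_impossible_packing_raises(self):
        spec = SceneSpec(height=32, width=32, cell_count=40, seed=0)
        with pytest.raises(RuntimeError, match="non-overlapping"):
            generate_normal(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(background_level=0.2, cell_darkness=0.5)


class TestInjectAnomaly:
    @pytest.fixture(scope="class")
    @staticmethod
    def base_image():
        return generate_normal(SceneSpec(seed=9))

    @pytest.mark.parametrize("kind", LOCALIZED)
    def test_outside_mask_bit_identical(self, base_image, kind):
        out, mask = inject_anomaly(base_image, AnomalySpec(kind=kind, severity=0.8, seed=2))
        outside = mask.pixels == 0
        assert outside.any()
        assert np.array_equal(out.pixels[outside], base_image.pixels[outside])

    @pytest.mark.parametrize("kind", WHOLE_FRAME)
    def test_whole_frame_kinds_mark_everything(self, base_image, kind):
        _, mask = inject_anomaly(base_image, AnomalySpec(kind=kind, severity=0.5, seed=2))
        assert np.all(mask.pixels == 1)

    @pytest.mark.parametrize("kind", ANOMALY_KINDS)
    def test_mask_nonempty_and_deterministic(self, base_image, kind):
        spec = AnomalySpec(kind=kind, severity=0.6, seed=4)
        out1, m1 = inject_anomaly(base_image, spec)
        out2, m2 = inject_anomaly(base_image, spec)
        assert m1.pixels.sum() > 0
        assert np.array_equal(out1.pixels, out2.pixels)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_single_artifact_blob_contains_center(self, base_image):
        spec = AnomalySpec(
            kind="artifact", severity=0.9, seed=0, center=(32.0, 32.0),
            radius=5.0, n_spots=1,
        )
        _, mask = inject_anomaly(base_image, spec)
        labels, n = ndimage.label(mask.pixels)
        assert n == 1
        assert mask.pixels[32, 32] == 1

    def test_blur_of_constant_image_is_identity(self):
        from autoqc.io_datasets import Image

        const = Image(pixels=np.full((64, 64), 0.7))
        out, mask = inject_anomaly(const, AnomalySpec(kind="z_shift", severity=0.8, seed=1))
        assert np.allclose(out.pixels, 0.7, atol=1e-12)
        assert np.all(mask.pixels == 1)

    def test_illumination_gain_matches_direct_recomputation(self, base_image):
        spec = AnomalySpec(kind="illumination", severity=0.4, seed=3, mode="gain")
        out, _ = inject_anomaly(base_image, spec)
        expected = np.clip(base_image.pixels * 1.4, 0.0, 1.0)
        assert np.allclose(out.pixels, expected, atol=1e-12)

    @pytest.mark.parametrize("kind", ANOMALY_KINDS)
    def test_severity_monotonicity_of_mean_change(self, base_image, kind):
        severities = [0.2, 0.4, 0.6, 0.8, 1.0]
        changes = []
        for s in severities:
            spec = AnomalySpec(kind=kind, severity=s, seed=11)
            out, mask = inject_anomaly(base_image, spec)
            inside = mask.pixels == 1
            changes.append(np.abs(out.pixels - base_image.pixels)[inside].mean())
        assert all(b >= a - 1e-12 for a, b in zip(changes, changes[1:]))

    def test_small_severity_gives_small_perturbation(self, base_image):
        out, _ = inject_anomaly(
            base_image, AnomalySpec(kind="contamination", severity=1e-3, seed=5)
        )
        assert np.abs(out.pixels - base_image.pixels).max() < 1e-2

    def test_out_of_frame_geometry_rejected(self, base_image):
        spec = AnomalySpec(kind="air_bubble", severity=0.5, seed=0, center=(2.0, 2.0), radius=20.0)
        with pytest.raises(ValueError, match="frame"):
            inject_anomaly(base_image, spec)

    def test_severity_zero_disallowed(self):
        with pytest.raises(ValueError):
            AnomalySpec(kind="artifact", severity=0.0)


class TestMakeBenchmark:
    def test_counts_and_masks(self, tmp_path):
        man = make_benchmark(tmp_path / "b", n_train=8, n_pos=4, n_neg_per_kind=1, base_seed=0)
        assert len(man.train_normal) == 8
        assert len(man.test_positive) == 4
        assert len(man.test_negative) == 5
        assert len(list((tmp_path / "b" / "test_negative" / "masks").iterdir())) == 5
        # manifest file readable and consistent
        man2 = read_manifest(tmp_path / "b" / "manifest.yaml")
        assert len(man2.test_negative) == 5

    def test_regeneration_is_byte_identical(self, tmp_path):
        make_benchmark(tmp_path / "a", 3, 2, 1, base_seed=5, n_val_normal=1,
                       n_val_abnormal_per_kind=1)
        make_benchmark(tmp_path / "b", 3, 2, 1, base_seed=5, n_val_normal=1,
                       n_val_abnormal_per_kind=1)
        files_a = sorted(p for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert [p.name for p in files_a] == [p.name for p in files_b]
        for pa, pb in zip(files_a, files_b):
            if pa.suffix == ".yaml":
                continue  # paths inside differ by root
            assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_no_negatives_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="classification"):
            make_benchmark(tmp_path / "c", 2, 1, 0, base_seed=1)

    def test_validation_split_written(self, tmp_path):
        man = make_benchmark(
            tmp_path / "d", 2, 1, 1, base_seed=2, n_val_normal=2,
            n_val_abnormal_per_kind=1,
        )
        labels = [lab for _, lab, _ in man.validation]
        assert labels.count("normal") == 2
        assert labels.count("abnormal") == 5
        assert all(m is not None for _, lab, m in man.validation if lab == "abnormal")
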