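"""Noise schedule, forward diffusion, patch machinery, DDPM training."""

import numpy as np
import pytest

from autoqc.diffusion import (
    DiffusionConfig,
    NoiseSchedule,
    forward_diffuse,
    reconstruct_ddpm,
    reconstruct_pddpm,
    train_ddpm,
    train_pddpm,
)
from autoqc.io_datasets import Image
from autoqc.recon_models import TrainConfig
from autoqc.scoring import patch_positions


@pytest.fixture(scope="module")
def schedule():
    return NoiseSchedule.linear(100, 1e-3, 0.2)


class TestNoiseSchedule:
    @pytest.mark.parametrize("T", [2, 5, 100, 1000])
    def test_linear_schedule_invariants(self, T):
        sch = NoiseSchedule.linear(T)
        assert sch.beta.shape == (T,)
        assert 0 < sch.beta[0] <= sch.beta[-1] < 1
        assert np.all(np.diff(sch.beta) >= 0)
        assert np.all((sch.alpha_bar > 0) & (sch.alpha_bar < 1))
        assert np.all(np.diff(sch.alpha_bar) < 0)
        # recurrence to machine precision
        assert np.allclose(
            sch.alpha_bar[1:], sch.alpha_bar[:-1] * sch.alpha[1:], rtol=1e-12
        )

    def test_decreasing_beta_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            NoiseSchedule(beta=np.array([0.2, 0.1]))

    def test_out_of_range_beta_rejected(self):
        with pytest.raises(ValueError):
            NoiseSchedule(beta=np.array([0.0, 0.1]))


class TestForwardDiffuse:
    def test_quarter_alpha_bar_halves_unit_image(self):
        # build a schedule whose abar at t=1 is exactly 0.25
        sch = NoiseSchedule(beta=np.array([0.75, 0.9]))
        xt = forward_diffuse(np.ones((4, 4)), 1, np.zeros((4, 4)), sch)
        assert np.allclose(xt, 0.5)

    def test_zero_noise_is_pure_scaling(self, schedule, rng):
        x0 = rng.uniform(-1, 1, size=(8, 8))
        for t in (1, 37, 100):
            xt = forward_diffuse(x0, t, np.zeros_like(x0), schedule)
            assert np.allclose(xt, np.sqrt(schedule.alpha_bar[t - 1]) * x0, rtol=1e-12)

    @pytest.mark.parametrize("t", [0, 101])
    def test_out_of_range_t_rejected(self, schedule, t):
        with pytest.raises(ValueError, match="t must be"):
            forward_diffuse(np.zeros((4, 4)), t, np.zeros((4, 4)), schedule)

    def test_monte_carlo_moments(self, schedule):
        """Sample mean -> sqrt(abar) x0 and variance -> 1 - abar within 3 SE."""
        rng = np.random.default_rng(7)
        t = 40
        x0 = 0.6
        n = 10_000
        draws = np.array(
            [forward_diffuse(np.array([[x0]]), t, rng.standard_normal((1, 1)), schedule)[0, 0]
             for _ in range(n)]
        )
        ab = schedule.alpha_bar[t - 1]
        se_mean = np.sqrt(1 - ab) / np.sqrt(n)
        assert abs(draws.mean() - np.sqrt(ab) * x0) < 3 * se_mean
        var = draws.var()
        se_var = (1 - ab) * np.sqrt(2.0 / (n - 1))
        assert abs(var - (1 - ab)) < 3 * se_var


class TestPatchMachinery:
    def test_exact_tiling_grid(self):
        assert patch_positions(64, 32, 32) == [0, 32]

    def test_edge_aligned_final_window(self):
        assert patch_positions(64, 32, 24) == [0, 24, 64 - 32]

    @pytest.mark.parametrize("seed", range(20))
    def test_coverage_counts_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(33, 97))
        p = int(rng.integers(8, h + 1))
        s = int(rng.integers(1, p + 1))
        pos = patch_positions(h, p, s)
        cov = np.zeros(h, dtype=int)
        for i in pos:
            cov[i : i + p] += 1
        # brute force: enumerate window membership over the same grid
        brute = np.array([sum(1 for i in pos if i <= k < i + p) for k in range(h)])
        assert np.array_equal(cov, brute)
        assert cov.min() >= 1  # every pixel covered

    def test_constant_denoiser_merge_is_constant(self, schedule):
        cfg = DiffusionConfig(schedule=schedule, t_test=50, patch_size=32,
                              patch_stride=24, seed=0)
        const = 0.3  # internal-frame output

        def denoiser(batch, t):
            return np.full_like(batch, const)

        out = reconstruct_pddpm(None, np.random.default_rng(0).uniform(size=(64, 64)),
                                cfg, denoiser=denoiser)
        assert np.allclose(out, (const + 1) / 2)

    def test_merge_permutation_invariance_via_average(self, schedule):
        """Overlap averaging is order-free: value depends only on the
        per-position outputs, checked against a hand-built accumulation."""
        cfg = DiffusionConfig(schedule=schedule, t_test=50, patch_size=32,
                              patch_stride=16, seed=3)
        calls = {}

        def denoiser(batch, t):
            out = np.random.default_rng(99).normal(size=batch.shape)
            calls["out"] = out
            return out

        img = np.random.default_rng(1).uniform(size=(64, 64))
        merged = reconstruct_pddpm(None, img, cfg, denoiser=denoiser)
        out = calls["out"]
        rows = patch_positions(64, 32, 16)
        acc = np.zeros((64, 64))
        cnt = np.zeros((64, 64))
        k = 0
        for i in rows:
            for j in rows:
                acc[i : i + 32, j : j + 32] += out[k, 0, i : i + 32, j : j + 32]
                cnt[i : i + 32, j : j + 32] += 1
                k += 1
        expected = np.clip(((acc / cnt) + 1) / 2, 0, 1)
        assert np.allclose(merged, expected)

    def test_stride_exceeding_patch_rejected(self, schedule):
        with pytest.raises(ValueError, match="stride"):
            DiffusionConfig(schedule=schedule, patch_size=16, patch_stride=24)


class TestTraining:
    def test_uniform_timestep_sampling(self):
        """t ~ U{1..T}: chi-square of the empirical histogram is sane."""
        rng = np.random.default_rng(0)
        T = 20
        draws = rng.integers(1, T + 1, size=10_000)
        counts = np.bincount(draws, minlength=T + 1)[1:]
        expected = 10_000 / T
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # df = 19; 99.9% quantile ~ 43.8
        assert chi2 < 43.8

    def test_x0_loss_zero_for_perfect_denoiser(self, schedule):
        x0 = np.random.default_rng(0).uniform(-1, 1, size=(2, 1, 8, 8))
        assert float(np.mean((x0 - x0) ** 2)) == 0.0

    @pytest.fixture(scope="class")
    @staticmethod
    def overfit_setup(schedule=None):
        sch = NoiseSchedule.linear(100, 1e-3, 0.2)
        diff = DiffusionConfig(schedule=sch, t_test=40, patch_size=16,
                               patch_stride=8, seed=0)
        cfg = TrainConfig(epochs=250, batch_size=3, learning_rate=2e-3,
                          base_width=8, n_levels=2, seed=0)
        return cfg, diff

    def test_ddpm_overfits_constant_images(self):
        # light-noise schedule: the tiny denoiser must recover which of the
        # three constants it was shown
        sch = NoiseSchedule.linear(20, 1e-3, 0.05)
        diff = DiffusionConfig(schedule=sch, t_test=10, seed=0)
        cfg = TrainConfig(epochs=300, batch_size=1, learning_rate=2e-3,
                          base_width=8, n_levels=2, seed=0)
        imgs = [Image(pixels=np.full((32, 32), v)) for v in (0.3, 0.5, 0.7)]
        model = train_ddpm(imgs, cfg, diff)
        for img in imgs:
            err = np.abs(model.reconstruct(img).pixels - img.pixels)
            assert err.mean() < 0.05

    def test_ddpm_single_image_memorization(self):
        from autoqc.synthetic_data import SceneSpec, generate_normal

        img = generate_normal(
            SceneSpec(height=32, width=32, cell_count=3, noise_sigma=0.0, seed=0)
        )
        sch = NoiseSchedule.linear(5, 1e-3, 0.01)
        diff = DiffusionConfig(schedule=sch, t_test=3, seed=0)
        cfg = TrainConfig(epochs=3000, batch_size=1, learning_rate=3e-3,
                          base_width=8, n_levels=2, seed=0)
        model = train_ddpm([img], cfg, diff)
        rec = model.reconstruct(img)
        assert np.abs(rec.pixels - img.pixels).max() < 0.1

    def test_reconstruct_deterministic_and_range_checked(self, tiny_normals, overfit_setup):
        cfg, diff = overfit_setup
        fast = TrainConfig(epochs=5, batch_size=3, learning_rate=2e-3,
                           base_width=8, n_levels=2, seed=0)
        model = train_ddpm(tiny_normals, fast, diff)
        img = tiny_normals[0]
        a = model.reconstruct(img).pixels
        b = model.reconstruct(img).pixels
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1
        with pytest.raises(ValueError):
            DiffusionConfig(schedule=diff.schedule, t_test=0)

    def test_pddpm_training_runs_and_reconstructs(self, tiny_normals, overfit_setup):
        cfg, diff = overfit_setup
        fast = TrainConfig(epochs=10, batch_size=3, learning_rate=2e-3,
                           base_width=8, n_levels=2, seed=0)
        model = train_pddpm(tiny_normals, fast, diff)
        rec = model.reconstruct(tiny_normals[0])
        assert rec.pixels.shape == (32, 32)
        assert rec.pixels.min() >= 0 and rec.pixels.max() <= 1


def test_pddpm_scores_higher_inside_localized_masks(desk_e2e):
    """Anomaly response: trained pDDPM's error maps are larger inside the
    ground-truth regions of localized defects than outside, on average."""
    from autoqc.io_datasets import load_image, load_mask
    from autoqc.scoring import score_map

    model = desk_e2e["pddpm_model"]
    ratios = []
    for img_path, mask_path in desk_e2e["manifest"].test_negative:
        mask = load_mask(mask_path)
        if mask.pixels.all():
            continue  # whole-frame defects have no outside region
        img = load_image(img_path)
        smap = score_map(img, model.reconstruct(img))
        inside = smap.values[mask.pixels == 1].mean()
        outside = smap.values[mask.pixels == 0].mean()
        ratios.append(inside / outside)
    assert len(ratios) >= 5
    assert np.mean(ratios) > 1.0
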