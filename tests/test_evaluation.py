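"""Image-quality metrics, the nearest baseline, and report harnesses."""
import math

import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from fdosr.evaluation import (
    MetricReport,
    evaluate_corpus,
    mse,
    nearest_baseline,
    psnr,
    rmse,
    ssim3d,
)
from fdosr.volume import Volume3D


def _vol(data):
    return Volume3D(np.asarray(data, dtype=np.float64))


class TestMse:
    def test_identity_and_symmetry(self, random_volume_16):
        other = _vol(np.random.default_rng(1).random((16, 16, 16)))
        assert mse(random_volume_16, random_volume_16.copy()) == 0.0
        assert mse(random_volume_16, other) == pytest.approx(
            mse(other, random_volume_16), rel=1e-15
        )

    def test_constant_offset_closed_form(self):
        a = _vol(np.full((8, 8, 8), 0.4))
        b = _vol(np.full((8, 8, 8), 0.5))
        assert mse(a, b) == pytest.approx(0.01, rel=1e-12)
        assert rmse(a, b) == pytest.approx(0.1, rel=1e-12)

    def test_dim_mismatch_raises(self, random_volume_16):
        with pytest.raises(ValueError):
            mse(random_volume_16, _vol(np.zeros((8, 8, 8))))


class TestPsnr:
    def test_closed_form_20db(self):
        a = _vol(np.full((8, 8, 8), 0.0))
        b = _vol(np.full((8, 8, 8), 0.1))  # mse = 0.01
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-12)

    def test_identical_volumes_give_inf_sentinel(self, random_volume_16):
        assert psnr(random_volume_16, random_volume_16.copy()) == math.inf

    def test_doubling_range_adds_six_db(self, random_volume_16):
        other = _vol(np.random.default_rng(2).random((16, 16, 16)))
        lo = psnr(random_volume_16, other, data_range=1.0)
        hi = psnr(random_volume_16, other, data_range=2.0)
        assert hi - lo == pytest.approx(20 * math.log10(2), abs=1e-9)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.random((16, 16, 16))
            b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
            assert psnr(_vol(a), _vol(b)) == pytest.approx(
                peak_signal_noise_ratio(a, b, data_range=1.0), abs=1e-6
            )


class TestSsim:
    def test_identical_volumes_give_one(self, random_volume_16):
        assert ssim3d(random_volume_16, random_volume_16.copy()) == 1.0

    def test_deterministic_on_seeded_noise(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((16, 16, 16)), rng.random((16, 16, 16))
        assert ssim3d(_vol(a), _vol(b)) == ssim3d(_vol(a), _vol(b))

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.random((16, 16, 16))
            b = np.clip(a + rng.normal(0, 0.08, a.shape), 0, 1)
            ref = structural_similarity(
                a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False,
            )
            assert ssim3d(_vol(a), _vol(b)) == pytest.approx(ref, abs=1e-4)

    def test_volume_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim3d(_vol(np.zeros((8, 8, 8))), _vol(np.zeros((8, 8, 8))))

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(6)
        a, b = rng.random((16, 16, 16)), rng.random((16, 16, 16))
        assert ssim3d(_vol(a), _vol(b)) <= 1.0


class TestNearestBaseline:
    def test_identity_scale_copies(self, random_volume_16):
        out = nearest_baseline(random_volume_16, 1.0)
        np.testing.assert_array_equal(out.data, random_volume_16.data)

    def test_factor_two_replicates_blocks(self):
        vol = _vol(np.arange(8, dtype=float).reshape(2, 2, 2))
        out = nearest_baseline(vol, 2.0)
        assert out.shape == (4, 4, 4)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    block = out.data[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
                    np.testing.assert_array_equal(block, vol.data[i, j, k])

    def test_copy_only_value_set(self, random_volume_16):
        out = nearest_baseline(random_volume_16, 2.7)
        assert set(np.unique(out.data)) <= set(np.unique(random_volume_16.data))


class TestEvaluateCorpus:
    def test_perfect_method_row(self, phantom_corpus_small):
        methods = {"oracle": lambda lr, s, dims: phantom_corpus_small[0][2]}
        report = evaluate_corpus(methods, phantom_corpus_small[:1], factors=[2.0])
        row = report.df.iloc[0]
        assert row["psnr_db"] == math.inf
        assert row["ssim"] == 1.0
        assert row["mse"] == 0.0

    def test_row_count_is_combinatorial(self, phantom_corpus_small):
        methods = {
            "nearest": lambda lr, s, dims: nearest_baseline(lr, s, dims),
            "oracle_blur": lambda lr, s, dims: nearest_baseline(lr, s, dims),
        }
        report = evaluate_corpus(methods, phantom_corpus_small, factors=[2.0, 2.5, 3.0])
        assert len(report.df) == len(phantom_corpus_small) * 3 * 2

    def test_rmse_squared_equals_mse_on_every_row(self, phantom_corpus_small):
        methods = {"nearest": lambda lr, s, dims: nearest_baseline(lr, s, dims)}
        report = evaluate_corpus(methods, phantom_corpus_small, factors=[2.0, 3.0])
        for _, row in report.df.iterrows():
            assert row["rmse"] ** 2 == pytest.approx(row["mse"], abs=1e-12)

    def test_psnr_decreasing_in_mse_across_rows(self, phantom_corpus_small):
        methods = {"nearest": lambda lr, s, dims: nearest_baseline(lr, s, dims)}
        report = evaluate_corpus(methods, phantom_corpus_small, factors=[2.0, 4.0])
        df = report.df.sort_values("mse")
        finite = df[np.isfinite(df["psnr_db"])]
        assert (np.diff(finite["psnr_db"]) <= 1e-12).all()

    def test_aggregate_excludes_inf_sentinels(self, phantom_corpus_small):
        methods = {"oracle": lambda lr, s, dims, c=phantom_corpus_small: next(
            v for i, p, v in c if v.shape == dims
        )}
        report = evaluate_corpus(methods, phantom_corpus_small[:2], factors=[2.0])
        agg = report.aggregate()
        assert not np.isinf(agg["psnr_db"]["mean"]).any()

    def test_markdown_table_renders(self, phantom_corpus_small):
        methods = {"nearest": lambda lr, s, dims: nearest_baseline(lr, s, dims)}
        report = evaluate_corpus(methods, phantom_corpus_small[:1], factors=[2.0])
        md = report.to_markdown("psnr_db")
        assert "| factor |" in md and "2.0X" in md


@pytest.fixture(scope="module")
def micro_setup():
    from conftest import MICRO_DECODER, MICRO_ENCODER
    from fdosr.phantom import make_corpus
    from fdosr.training import desk_training_config

    train_vols = [v for _, _, v in make_corpus(2, (32, 32, 32), base_seed=20)]
    test_corpus = make_corpus(1, (32, 32, 32), base_seed=40)
    cfg = desk_training_config(seed=0, epochs=2, max_steps=4)
    return train_vols, test_corpus, cfg, MICRO_ENCODER, MICRO_DECODER


class TestAblationLambda:
    def test_single_lambda_sweep_produces_rows(self, micro_setup):
        from fdosr.evaluation import ablation_lambda

        train_vols, test_corpus, cfg, enc, dec = micro_setup
        report = ablation_lambda(train_vols, test_corpus, [1e-3], cfg, enc, dec,
                                 factors=[2.0])
        assert len(report.df) == 1
        assert (report.df["status"] == "ok").all()
        assert report.df["method"].iloc[0] == "lambda=0.001"

    def test_determinism_for_repeated_lambda(self, micro_setup):
        from fdosr.evaluation import ablation_lambda

        train_vols, test_corpus, cfg, enc, dec = micro_setup
        a = ablation_lambda(train_vols, test_corpus, [0.0], cfg, enc, dec, factors=[2.0])
        b = ablation_lambda(train_vols, test_corpus, [0.0], cfg, enc, dec, factors=[2.0])
        assert a.df["psnr_db"].tolist() == b.df["psnr_db"].tolist()

    def test_divergence_recorded_as_status_not_raised(self, micro_setup):
        from dataclasses import replace
        from fdosr.evaluation import ablation_lambda
        from fdosr.network import DecoderConfig, EncoderConfig
        from fdosr.phantom import make_corpus

        _, test_corpus, cfg, _, _ = micro_setup
        enc = EncoderConfig(n_rdb=2, layers_per_rdb=2, base_channels=8,
                            growth_channels=4, feature_dim=8)
        dec = DecoderConfig(n_layers=3, hidden_width=8)
        train_vols = [v for _, _, v in make_corpus(4, (32, 32, 32), base_seed=1)]
        bad_cfg = replace(cfg, lr_initial=0.2, grad_clip=None, epochs=60, max_steps=240)
        report = ablation_lambda(train_vols, test_corpus, [10.0], bad_cfg, enc, dec,
                                 factors=[2.0])
        assert (report.df["status"] == "diverged").all()
        assert report.df["psnr_db"].isna().all()

    def test_default_lambda_grid_spans_ablation_range(self):
        from fdosr.evaluation import DEFAULT_LAMBDAS

        assert DEFAULT_LAMBDAS == (1e-2, 1e-3, 1e-5, 1e-10, 1e-15)
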