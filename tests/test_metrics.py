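"""PSNR/SSIM fidelity, symmetry, and the noise-level sweep report."""

import json

import numpy as np
import pytest

from mrdenoise.metrics import MetricsReport, SSIMConstants, evaluate_sweep, mse_metric, psnr, ssim
from mrdenoise.network import DenoisingNetwork, tiny_model_spec
from mrdenoise.phantom import generate_phantom


def brute_force_psnr(f, d):
    """Direct transcription of the metric definitions, loop form."""
    f = np.asarray(f) * 255.0
    d = np.asarray(d) * 255.0
    m, n = f.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            total += (f[i, j] - d[i, j]) ** 2
    mse = total / (m * n)
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(255.0**2 / mse)


def brute_force_ssim(f, d, C1=(0.01 * 255) ** 2, C2=(0.03 * 255) ** 2, C3=(0.03 * 255) ** 2 / 2):
    f = np.asarray(f) * 255.0
    d = np.asarray(d) * 255.0
    mn = f.size
    mu_f = sum(f.flat) / mn
    mu_d = sum(d.flat) / mn
    var_f = sum((x - mu_f) ** 2 for x in f.flat) / mn
    var_d = sum((x - mu_d) ** 2 for x in d.flat) / mn
    cov = sum((x - mu_f) * (y - mu_d) for x, y in zip(f.flat, d.flat)) / mn
    sig_f, sig_d = np.sqrt(var_f), np.sqrt(var_d)
    l = (2 * mu_f * mu_d + C1) / (mu_f**2 + mu_d**2 + C1)
    c = (2 * sig_f * sig_d + C2) / (sig_f**2 + sig_d**2 + C2)
    s = (cov + C3) / (sig_f * sig_d + C3)
    return l * c * s


class TestMseMetric:
    @pytest.mark.parametrize(
        "fval,dval,expected",
        [(0.0, 0.0, 0.0), (0.0, 1.0, 65025.0), (0.0, 128 / 255, 16384.0)],
    )
    def test_constant_image_hand_values(self, fval, dval, expected):
        f = np.full((8, 8), fval)
        d = np.full((8, 8), dval)
        assert mse_metric(f, d) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_metric(np.zeros((4, 4)), np.zeros((4, 5)))


class TestPsnr:
    def test_identical_images_give_infinity(self):
        f = generate_phantom(32, 32, 3, seed=1)
        assert psnr(f, f) == float("inf")

    def test_full_range_difference_is_zero_db(self):
        assert psnr(np.zeros((8, 8)), np.ones((8, 8))) == pytest.approx(0.0)

    def test_half_range_hand_value(self):
        # MSE = 128^2 -> 10*log10(65025/16384) ~ 5.99 dB
        value = psnr(np.zeros((8, 8)), np.full((8, 8), 128 / 255))
        assert value == pytest.approx(10 * np.log10(65025 / 16384), rel=1e-12)

    def test_symmetry(self, rng):
        f, d = rng.random((16, 16)), rng.random((16, 16))
        assert psnr(f, d) == psnr(d, f)

    def test_decreases_with_noise_variance(self):
        clean = generate_phantom(64, 64, 4, seed=2)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1, clean.shape)
        values = [psnr(clean, clean + s * noise) for s in (0.01, 0.03, 0.1, 0.3)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSsim:
    def test_identical_images_give_one_exactly(self):
        f = generate_phantom(32, 32, 3, seed=1)
        assert ssim(f, f) == 1.0

    def test_constant_zero_vs_constant_one(self):
        # zero variance: c = s = 1, l = C1 / (255^2 + C1)
        C1 = (0.01 * 255) ** 2
        value = ssim(np.zeros((8, 8)), np.ones((8, 8)))
        assert value == pytest.approx(C1 / (255.0**2 + C1), rel=1e-12)

    def test_independent_noise_images_near_zero(self):
        rng = np.random.default_rng(3)
        f = rng.random((256, 256))
        d = rng.random((256, 256))
        # zero mean-pair covariance and mismatched means both small here;
        # the structure term dominates and has zero expectation
        assert abs(ssim(f, d)) < 0.2

    def test_symmetry(self, rng):
        f, d = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(f, d) == pytest.approx(ssim(d, f), rel=1e-14)

    def test_at_most_one_with_equality_iff_identical(self, rng):
        f = rng.random((16, 16))
        for _ in range(20):
            d = rng.random((16, 16))
            assert ssim(f, d) < 1.0
        assert ssim(f, f.copy()) == 1.0

    def test_anticorrelated_images_can_go_negative(self):
        f = np.tile([0.0, 1.0], (16, 8))
        d = 1.0 - f
        assert ssim(f, d) < 0.0

    def test_agrees_with_brute_force_transcription(self, rng):
        for _ in range(20):
            f, d = rng.random((16, 16)), rng.random((16, 16))
            assert ssim(f, d) == pytest.approx(brute_force_ssim(f, d), abs=1e-10)
            assert psnr(f, d) == pytest.approx(brute_force_psnr(f, d), abs=1e-10)

    def test_windowed_variant_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity

        f, d = rng.random((32, 32)), rng.random((32, 32))
        expected = structural_similarity(f * 255, d * 255, data_range=255.0)
        assert ssim(f, d, windowed=True) == pytest.approx(expected, rel=1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            SSIMConstants(C1=0.0)


@pytest.fixture(scope="module")
def identity_model():
    return DenoisingNetwork(tiny_model_spec())  # zero reconstruction


@pytest.fixture(scope="module")
def clean_images():
    return [generate_phantom(48, 48, 4, seed=s) for s in range(3)]


class TestEvaluateSweep:
    def test_identity_model_reproduces_noisy_baseline(self, identity_model, clean_images):
        report = evaluate_sweep(identity_model, clean_images, [4.0, 7.0], seed=1)
        # identity model: denoised == noisy, so metrics equal the baseline
        from mrdenoise.phantom import NoiseSpec, add_noise

        ss = np.random.SeedSequence(1)
        for percent in [4.0, 7.0]:
            vals = []
            for img, child in zip(clean_images, ss.spawn(len(clean_images))):
                pair = add_noise(
                    img,
                    NoiseSpec(percent=percent, seed=int(child.generate_state(1)[0] % 2**31)),
                )
                vals.append(psnr(img, pair.noisy))
            assert report.row(percent)[0] == pytest.approx(np.mean(vals))

    def test_zero_noise_gives_flagged_infinite_psnr_and_unit_ssim(
        self, identity_model, clean_images
    ):
        report = evaluate_sweep(identity_model, clean_images, [0.0], seed=1)
        assert report.row(0.0)[0] == float("inf")
        assert report.row(0.0)[1] == 1.0

    def test_rows_sorted_by_noise_percent(self, identity_model, clean_images):
        report = evaluate_sweep(identity_model, clean_images, [7.0, 1.0, 4.0], seed=1)
        assert report.noise_percents == [1.0, 4.0, 7.0]

    def test_report_serialization(self, identity_model, clean_images):
        report = evaluate_sweep(identity_model, clean_images, [4.0], seed=1)
        d = report.to_dict()
        assert d["rows"][0]["noise_percent"] == 4.0
        csv = report.to_csv()
        assert csv.splitlines()[0] == "noise_percent,method,mean_psnr,mean_ssim"
        assert len(csv.splitlines()) == 2
        json.dumps(d)  # serializable

    def test_empty_test_set_rejected(self, identity_model):
        with pytest.raises(ValueError):
            evaluate_sweep(identity_model, [], [7.0])
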