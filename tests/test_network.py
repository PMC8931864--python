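"""Residual U-Net architecture, data plumbing, training, and weight I/O."""

import numpy as np
import pytest
from scipy import stats

from cimphase.nn import (DpmToSlimTranslator, NetConfig, TrainConfig, TranslationResults,
                         build_model, count_parameters, random_crop_pair, scale_to_unit,
                         split_pairs, unit_to_phase)
from cimphase.types import PhaseMap


class TestArchitecture:
    def test_parameter_budget(self):
        assert count_parameters(build_model(NetConfig())) <= 3_300_000

    def test_parameter_count_independent_of_input_size(self):
        m = build_model(NetConfig(), seed=0)
        n0 = count_parameters(m)
        m.forward(np.zeros((1, 1, 32, 32)))
        m.forward(np.zeros((1, 1, 64, 64)))
        assert count_parameters(m) == n0

    @pytest.mark.parametrize("side", [400, 100])
    def test_output_shape_equals_input_shape(self, side):
        m = build_model(NetConfig(), seed=0)
        out = m.predict_image(np.zeros((side, side)))
        assert out.shape == (side, side)

    def test_zero_weights_give_zero_output(self):
        m = build_model(NetConfig(), seed=0)
        state = m.state_dict()
        for k in state:
            if not k.endswith("bn_var"):
                state[k] = np.zeros_like(state[k])
        m.load_state_dict(state)
        out = m.predict_image(np.random.default_rng(0).standard_normal((32, 32)))
        assert np.allclose(out, 0.0)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            NetConfig(encoder_channels=(16, 32, 64))
        with pytest.raises(ValueError):
            NetConfig(conv_kernel=5)
        with pytest.raises(ValueError):
            NetConfig(dropout_rate=1.5)


class TestScaling:
    def test_affine_endpoints(self):
        assert scale_to_unit(np.array(-np.pi)) == pytest.approx(0.0)
        assert scale_to_unit(np.array(0.0)) == pytest.approx(0.5)
        assert scale_to_unit(np.array(np.pi)) == pytest.approx(1.0)

    def test_round_trip_in_range(self):
        x = np.linspace(-np.pi, np.pi, 101)
        assert np.allclose(unit_to_phase(scale_to_unit(x)), x, atol=1e-12)

    def test_out_of_range_clipped_and_counted(self):
        scaled, n = scale_to_unit(np.array([1.2 * np.pi, 0.0]), return_clip_count=True)
        assert n == 1
        assert scaled[0] == pytest.approx(1.0)


class TestRandomCrop:
    def test_full_size_is_identity(self):
        img = np.arange(64.0).reshape(8, 8)
        a, b = random_crop_pair(img, img, size=8, rng=0)
        assert np.array_equal(a, img) and np.array_equal(b, img)

    def test_seeded_window_repeatable(self):
        img = np.random.default_rng(0).standard_normal((64, 64))
        a1, _ = random_crop_pair(img, img, size=16, rng=5)
        a2, _ = random_crop_pair(img, img, size=16, rng=5)
        assert np.array_equal(a1, a2)

    def test_offsets_uniform_over_valid_range(self):
        # chi-square uniformity of the top offset over [0, H - size] at alpha = 0.01
        rng = np.random.default_rng(1)
        img = np.arange(100.0 * 100.0).reshape(100, 100)  # value encodes position
        n_bins = 100 - 36 + 1
        counts = np.zeros(n_bins)
        draws = 10000
        for _ in range(draws):
            a, _ = random_crop_pair(img, img, size=36, rng=rng)
            top = int(a[0, 0]) // 100
            counts[top] += 1
        chi2 = ((counts - draws / n_bins) ** 2 / (draws / n_bins)).sum()
        p = stats.chi2.sf(chi2, n_bins - 1)
        assert p > 0.01

    def test_window_identical_across_pair(self):
        rng = np.random.default_rng(3)
        a = np.random.default_rng(4).standard_normal((40, 40))
        b = a * 2 + 1
        ca, cb = random_crop_pair(a, b, size=16, rng=rng)
        assert np.allclose(cb, ca * 2 + 1)


class TestSplit:
    def test_disjoint_and_complete(self):
        s = split_pairs(20, seed=0)
        all_idx = np.concatenate([s["train"], s["val"], s["test"]])
        assert sorted(all_idx.tolist()) == list(range(20))

    def test_default_ratio(self):
        s = split_pairs(50, seed=1)
        assert len(s["train"]) == 40 and len(s["val"]) == 5 and len(s["test"]) == 5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            split_pairs(1)


def _identity_pairs(n=6, side=64, seed=0):
    rng = np.random.default_rng(seed)
    from scipy import ndimage
    out = []
    for _ in range(n):
        img = ndimage.gaussian_filter(rng.standard_normal((side, side)), 4)
        img *= 0.8 / np.abs(img).max()
        out.append((img, img))
    return out


class TestTraining:
    def test_loss_decreases_on_learnable_task(self):
        pairs = _identity_pairs(6)
        tc = TrainConfig(lr=1e-3, batch_size=2, epochs=5, crop=48, seed=0)
        res = DpmToSlimTranslator(pairs, train_config=tc).fit()
        assert res.history.train_loss.iloc[-1] < res.history.train_loss.iloc[0]
        assert len(res.history) == 5
        assert res.best_epoch == int(res.history.val_loss.idxmin())

    def test_identity_task_converges(self):
        # input == target is exactly representable; validation loss must
        # collapse within 50 epochs
        pairs = _identity_pairs(6, seed=1)
        tc = TrainConfig(lr=2e-3, batch_size=2, epochs=50, crop=48, seed=0)
        res = DpmToSlimTranslator(pairs, train_config=tc).fit()
        assert res.history.val_loss.min() < 1e-4

    def test_empty_partition_rejected(self):
        pairs = _identity_pairs(4)
        with pytest.raises(ValueError):
            DpmToSlimTranslator(pairs, split={"train": [0, 1], "val": [], "test": [3]})

    def test_inference_deterministic_and_tagged(self):
        pairs = _identity_pairs(4)
        tc = TrainConfig(lr=1e-3, batch_size=2, epochs=2, crop=48, seed=0)
        res = DpmToSlimTranslator(pairs, train_config=tc).fit()
        pm = PhaseMap(pairs[0][0], "DPM", 0.623)
        out1 = res.predict(pm)
        out2 = res.predict(pm)
        assert out1.modality == "CIM"
        assert out1.phase.shape == pm.phase.shape
        assert np.array_equal(out1.phase, out2.phase)  # no dropout at inference

    def test_tiled_inference_matches_whole_image_interior(self):
        pairs = _identity_pairs(4)
        tc = TrainConfig(lr=1e-3, batch_size=2, epochs=2, crop=48, seed=0)
        res = DpmToSlimTranslator(pairs, train_config=tc).fit()
        img = _identity_pairs(1, side=128, seed=9)[0][0]
        whole = res.model.predict_image(scale_to_unit(img))
        tile = res.model.predict_image(scale_to_unit(img[16:112, 16:112]))
        # the network is fully convolutional, so tile and whole-image outputs
        # agree up to boundary influence, which decays away from the tile edge
        # (the nominal receptive field exceeds the tile, so agreement is
        # asymptotic rather than exact)
        interior = np.abs(whole[48:80, 48:80] - tile[32:64, 32:64])
        everywhere = np.abs(whole[16:112, 16:112] - tile)
        assert interior.max() < 5e-3
        assert interior.max() < everywhere.max()


@pytest.fixture(scope="module")
def fitted():
    pairs = _identity_pairs(4)
    tc = TrainConfig(lr=1e-3, batch_size=2, epochs=2, crop=48, seed=0)
    return DpmToSlimTranslator(pairs, train_config=tc).fit()


class TestWeightInterchange:
    def test_round_trip_bit_exact(self, fitted, tmp_path):
        p = tmp_path / "w.h5"
        fitted.save(p)
        loaded = TranslationResults.load(p)
        for k, v in fitted.model.state_dict().items():
            assert np.array_equal(loaded.model.state_dict()[k], v), k
        img = np.random.default_rng(0).standard_normal((48, 48)) * 0.5
        assert np.array_equal(fitted.predict(img).phase, loaded.predict(img).phase)

    def test_file_enumerates_only_weight_groups(self, fitted, tmp_path):
        import h5py
        p = tmp_path / "w.h5"
        fitted.save(p)
        allowed = {"kernel", "bias", "bn_gamma", "bn_beta", "bn_mean", "bn_var"}
        with h5py.File(p) as f:
            assert set(f.keys()) == {"layers", "config", "history"}
            leaves = []
            f["layers"].visititems(
                lambda path, obj: leaves.append(path) if isinstance(obj, h5py.Dataset) else None)
            assert leaves
            assert all(path.rpartition("/")[2] in allowed for path in leaves)

    def test_tampered_shape_raises_named_error(self, fitted, tmp_path):
        import h5py
        p = tmp_path / "w.h5"
        fitted.save(p)
        with h5py.File(p, "r+") as f:
            del f["layers/head/kernel"]
            f["layers/head"].create_dataset("kernel", data=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="head"):
            TranslationResults.load(p)

    def test_history_and_config_survive(self, fitted, tmp_path):
        p = tmp_path / "w.h5"
        fitted.save(p)
        loaded = TranslationResults.load(p)
        assert loaded.best_epoch == fitted.best_epoch
        assert np.allclose(loaded.history.val_loss, fitted.history.val_loss)
        assert loaded.net_config == fitted.net_config

    def test_summary_mentions_key_facts(self, fitted):
        s = fitted.summary()
        assert "trainable parameters" in s and "best epoch" in s
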