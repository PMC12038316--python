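"""End-to-end training protocol and the inference pass."""

import numpy as np
import pytest

import scenenet as sn
from scenenet.stimuli import GrayImage
from scenenet.training import TrainingSchedule

FAST = TrainingSchedule(n_epochs=2, n_update_presentations=2,
                        n_buildup_presentations=1)


def _fast_model(seed=0, **overrides):
    cfg = sn.make_config({"seed": seed, **overrides})
    return sn.build_model(cfg)


class TestDeterminism:
    def test_same_seed_bit_identical_weights(self, glyph_scene):
        models = []
        for _ in range(2):
            m = _fast_model(3)
            sn.train(m, glyph_scene, FAST, rng=7)
            models.append(m)
        a, b = models
        np.testing.assert_array_equal(a.conn_v1_l1.weights, b.conn_v1_l1.weights)
        np.testing.assert_array_equal(a.conn_l2_l3.weights, b.conn_l2_l3.weights)
        np.testing.assert_array_equal(a.recurrent.W, b.recurrent.W)

    def test_present_is_pure(self, glyph_model):
        img = sn.digits_patch()
        a = sn.present(glyph_model, img, "UL")
        b = sn.present(glyph_model, img, "UL")
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])


class TestForwardPass:
    def test_black_image_silences_every_layer(self, glyph_model):
        out = sn.present(glyph_model, GrayImage(np.zeros((256, 256))), "UL")
        for key in ("layer1", "layer2", "layer3"):
            assert not out[key].any()

    def test_each_layer_meets_its_sparseness_target(self, glyph_model):
        out = sn.present(glyph_model, sn.digits_patch(), "UL")
        for key, cfg in zip(("layer1", "layer2", "layer3"),
                            glyph_model.layer_cfgs):
            assert sn.sparseness(out[key]) == pytest.approx(cfg.sparseness,
                                                            abs=1e-3)

    def test_layer3_support_confined_to_gaze_quadrant(self, glyph_model):
        out = sn.present(glyph_model, sn.digits_patch(), "UL")
        rows, cols = np.nonzero(out["layer3"] > 0)
        frac_in = np.mean((rows < 16) & (cols < 16))
        assert frac_in >= 0.9

    def test_trained_patches_evoke_rates_everywhere(self, glyph_model,
                                                    glyph_scene):
        for quadrant, patch in glyph_scene.items():
            out = sn.present(glyph_model, patch, quadrant)
            for key in ("layer1", "layer2", "layer3"):
                assert out[key].any(), (quadrant, key)


class TestTrainingInvariants:
    def test_weight_norms_unit_after_full_training(self, glyph_model):
        for conn in (glyph_model.conn_v1_l1, glyph_model.conn_l1_l2,
                     glyph_model.conn_l2_l3):
            np.testing.assert_allclose(np.linalg.norm(conn.weights, axis=1),
                                       1.0, atol=1e-9)

    def test_distinct_populations_per_patch(self, glyph_model):
        o1 = sn.present(glyph_model, sn.digits_patch(), "UL")
        o2 = sn.present(glyph_model, sn.letters_patch(), "UR")
        for key in ("layer1", "layer2"):
            a, b = o1[key] > 0, o2[key] > 0
            overlap = (a & b).sum() / min(a.sum(), b.sum())
            assert overlap < 0.5, key

    def test_best_patch_tuning_grows_over_epochs(self, glyph_scene):
        # training is monotone: a neuron's tuning to its preferred patch
        # (pre-threshold activation, which is not confounded by the
        # per-presentation threshold) does not decrease from epoch 1 to 7
        # for at least 80% of the initially active neurons
        from scenenet import competitive as comp

        m = _fast_model(1)
        sched = TrainingSchedule(n_epochs=1)

        def best_activation():
            h1 = comp.activate(m.encode(sn.digits_patch()).responses,
                               m.conn_v1_l1)
            h2 = comp.activate(m.encode(sn.letters_patch()).responses,
                               m.conn_v1_l1)
            return np.maximum(h1, h2)

        sn.train(m, glyph_scene, sched, rng=5)
        early = best_activation()
        active = np.maximum(
            sn.present(m, sn.digits_patch(), "UL")["layer1"],
            sn.present(m, sn.letters_patch(), "UR")["layer1"],
        ) > 0
        for _ in range(6):
            sn.train(m, glyph_scene, sched, rng=5)
        late = best_activation()
        assert np.mean(late[active] >= early[active] * 0.999) >= 0.8

    def test_empty_scene_rejected(self):
        with pytest.raises(ValueError):
            sn.SceneSpec({})

    def test_simultaneous_mode_runs(self, glyph_scene):
        m = _fast_model(2, training={"sequential": False, "n_epochs": 1,
                                     "n_update_presentations": 1,
                                     "n_buildup_presentations": 1})
        sn.train(m, glyph_scene)
        assert sn.present(m, sn.digits_patch(), "UL")["layer3"].any()

    def test_jitter_augmentation_runs(self, glyph_scene):
        m = _fast_model(2, training={"jitter": {"enabled": True},
                                     "n_epochs": 1,
                                     "n_update_presentations": 1,
                                     "n_buildup_presentations": 1})
        sn.train(m, glyph_scene)
        assert sn.present(m, sn.digits_patch(), "UL")["layer1"].any()


class TestArchive:
    def test_save_load_roundtrip(self, tmp_path, glyph_scene):
        m = _fast_model(4)
        sn.train(m, glyph_scene, FAST, rng=1)
        sn.save_model(m, tmp_path / "model")
        back = sn.load_model(tmp_path / "model")
        np.testing.assert_array_equal(m.conn_v1_l1.weights,
                                      back.conn_v1_l1.weights)
        np.testing.assert_array_equal(m.recurrent.W, back.recurrent.W)
        a = sn.present(m, sn.digits_patch(), "UL")
        b = sn.present(back, sn.digits_patch(), "UL")
        np.testing.assert_array_equal(a["layer3"], b["layer3"])
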