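import numpy as np
import pytest

from rriguard.aed import BeatLabel, DetectionThresholds
from rriguard.daem import (
    ModificationRecord,
    _repair_window,
    build_dae_training_pairs,
    modify_event,
    repair_rde,
    run_pipeline,
    train_dae_pair,
)
from rriguard.neuralnet import AEModel, TrainConfig, forward
from rriguard.rri_data import RRISeries
from rriguard.synthgen import inject_pac, inject_pvc, inject_rde, simulate_normal_rri


def constant_output_model(role: str, value: float) -> AEModel:
    """Zero weights and output bias = value/scale: DAE(x) == value for all x."""
    h = {"AE": 3, "DAE_PVC": 2, "DAE_PAC": 2, "DAE_RDE": 8}[role]
    act = "relu" if role in ("DAE_PVC", "DAE_PAC") else "sigmoid"
    m = AEModel(
        W1=np.zeros((h, 4)),
        b1=np.zeros(h),
        W2=np.zeros((4, h)),
        b2=np.full(4, value / 100.0),
        hidden_activation=act,
        role=role,
    )
    return m


class TestRepairWindow:
    def test_constant_offset_is_spread_evenly(self):
        # DAE output = +10 ms on every slot -> d = 40, each element -10
        m = constant_output_model("DAE_PVC", 10.0)
        x = np.array([800.0, 600.0, 1000.0, 800.0])
        x_tilde, d = _repair_window(m, x)
        assert d == pytest.approx(40.0)
        assert np.allclose(x_tilde, x.mean())

    def test_window_sum_conserved_for_any_model(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            from rriguard.neuralnet import init_model

            m = init_model("DAE_PVC", seed=seed)
            x = rng.uniform(500, 1100, size=4)
            x_tilde, _ = _repair_window(m, x)
            assert np.sum(x_tilde) == pytest.approx(np.sum(x), abs=1e-9)


class TestModifyEvent:
    def test_record_conserves_window_time(self, dae_models):
        clean = simulate_normal_rri(200, seed=1)
        dirty, _ = inject_pvc(clean, 100, 250.0)
        rec = modify_event(dae_models, BeatLabel(100, "PVC", 99.0), dirty)
        assert np.sum(rec.modified) == pytest.approx(np.sum(rec.original), abs=1e-6)

    def test_wrong_label_type_rejected(self, dae_models):
        s = simulate_normal_rri(50, seed=2)
        with pytest.raises(ValueError, match="PVC/PAC"):
            modify_event(dae_models, BeatLabel(10, "RDE", 99.0), s)

    def test_window_at_edge_rejected(self, dae_models):
        s = simulate_normal_rri(50, seed=3)
        with pytest.raises(ValueError, match="bounds"):
            modify_event(dae_models, BeatLabel(48, "PVC", 99.0), s)

    def test_record_invariant_enforced(self):
        with pytest.raises(ValueError, match="conserve"):
            ModificationRecord(
                0, "PVC", np.array([800.0] * 4), np.array([900.0] * 4), 0.0
            )


class TestPipeline:
    def test_clean_series_unchanged(self, ae_model, thresholds, dae_models):
        clean = simulate_normal_rri(2000, seed=4)
        out, labels, records = run_pipeline(ae_model, thresholds, dae_models, clean)
        assert records == []
        assert np.array_equal(out.rri, clean.rri)

    def test_pvc_repair_moves_series_toward_truth(
        self, ae_model, thresholds, dae_models
    ):
        clean = simulate_normal_rri(2000, seed=5)
        dirty, _ = inject_pvc(clean, 1000, 300.0)
        out, labels, records = run_pipeline(ae_model, thresholds, dae_models, dirty)
        assert len(records) == 1
        err_before = np.sqrt(np.mean((dirty.rri - clean.rri) ** 2))
        err_after = np.sqrt(np.mean((out.rri - clean.rri) ** 2))
        assert err_after < err_before

    def test_total_time_conserved_by_modifications(
        self, ae_model, thresholds, dae_models
    ):
        clean = simulate_normal_rri(2000, seed=6)
        dirty, _ = inject_pvc(clean, 700, 280.0)
        out, _, _ = run_pipeline(ae_model, thresholds, dae_models, dirty)
        assert out.rri.sum() == pytest.approx(dirty.rri.sum(), abs=1e-6)

    def test_rerun_on_own_output_is_stable(self, ae_model, thresholds, dae_models):
        clean = simulate_normal_rri(3000, seed=7)
        dirty, _ = inject_pvc(clean, 1500, 320.0)
        once, _, _ = run_pipeline(ae_model, thresholds, dae_models, dirty)
        twice, _, records = run_pipeline(ae_model, thresholds, dae_models, once)
        assert len(records) == 0
        assert np.array_equal(twice.rri, once.rri)


class TestDAETraining:
    def test_pairs_center_on_contaminated_mean(self):
        clean = simulate_normal_rri(500, seed=8)
        X_in, X_target = build_dae_training_pairs(clean, "PVC", n_events=50, seed=9)
        assert np.allclose(X_in.mean(axis=1), 0.0, atol=1e-9)
        # PVC conserves the window sum, so targets are centered too
        assert np.allclose(X_target.mean(axis=1), 0.0, atol=1e-9)

    def test_pac_targets_offset_by_quarter_height(self):
        clean = simulate_normal_rri(500, seed=10)
        X_in, X_target = build_dae_training_pairs(clean, "PAC", n_events=50, seed=11)
        # removing H from one slot drops the contaminated mean by H/4, so
        # the clean target has mean +H/4 in centered coordinates
        offsets = X_target.mean(axis=1)
        assert np.all(offsets > 100.0 / 4 - 1e-9)
        assert np.all(offsets < 370.0 / 4 + 1e-9)

    def test_trained_dae_beats_identity_on_held_out_windows(self, dae_models):
        clean = simulate_normal_rri(1000, seed=12)
        X_in, X_target = build_dae_training_pairs(clean, "PVC", n_events=200, seed=13)
        pred = forward(dae_models["DAE_PVC"], X_in)
        err_model = np.median(np.linalg.norm(pred - X_target, axis=1))
        err_identity = np.median(np.linalg.norm(X_in - X_target, axis=1))
        assert err_model < err_identity

    def test_model_specificity(self, dae_models):
        """The PAC model underperforms the PVC model on PVC windows."""
        clean = simulate_normal_rri(1000, seed=14)
        X_in, X_target = build_dae_training_pairs(clean, "PVC", n_events=200, seed=15)
        err = {
            role: np.median(
                np.linalg.norm(forward(dae_models[role], X_in) - X_target, axis=1)
            )
            for role in ("DAE_PVC", "DAE_PAC")
        }
        assert err["DAE_PVC"] < err["DAE_PAC"]

    def test_training_seed_deterministic(self):
        clean = simulate_normal_rri(600, seed=16)
        cfg = TrainConfig(seed=17, epochs=300)
        a = train_dae_pair(clean, "PVC", cfg=cfg, n_events=100)
        b = train_dae_pair(clean, "PVC", cfg=cfg, n_events=100)
        assert np.array_equal(a.W1, b.W1)


class TestRepairRDE:
    def test_split_restores_beat_count_and_time(self):
        clean = simulate_normal_rri(600, seed=18)
        rde_model = train_dae_pair(
            clean, "RDE", cfg=TrainConfig(seed=19), n_events=300
        )
        test = simulate_normal_rri(200, seed=20)
        merged, _ = inject_rde(test, 100)
        repaired, rec = repair_rde(rde_model, merged, 100)
        assert len(repaired) == len(test)
        assert repaired.rri.sum() == pytest.approx(test.rri.sum(), abs=1e-6)
        # the split should approximate the two true intervals
        assert abs(repaired.rri[100] - test.rri[100]) < abs(
            merged.rri[100] - test.rri[100]
        )

    def test_requires_rde_model(self, dae_models):
        s = simulate_normal_rri(100, seed=21)
        with pytest.raises(ValueError, match="DAE_RDE"):
            repair_rde(dae_models["DAE_PVC"], s, 50)
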