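"""Tests for the loss functions and the three-phase curriculum."""

import json

import numpy as np
import pytest

from pulsemil import autograd as ag
from pulsemil import bvpsynth, sessionio
from pulsemil import curriculum as cur
from pulsemil.autograd import Tensor
from pulsemil.network import Model, canonical_config


def supcon_enumeration_oracle(z, labels, tau):
    """Direct per-anchor enumeration of the supervised contrastive loss."""
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    per_anchor = []
    for i in range(n):
        pos = [p for p in range(n) if p != i and labels[p] == labels[i]]
        if not pos:
            continue
        denom = sum(np.exp(z[i] @ z[a] / tau) for a in range(n) if a != i)
        total = sum(np.log(np.exp(z[i] @ z[p] / tau) / denom) for p in pos)
        per_anchor.append(-total / len(pos))
    return float(np.mean(per_anchor))


class TestSupConLoss:
    def test_worked_two_positive_case(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        loss = cur.supcon_loss(z, ["A", "A", "B"], tau=1.0)
        assert loss.item() == pytest.approx(np.log(1 + np.exp(-1.0)), abs=1e-6)
        assert loss.item() == pytest.approx(0.31326, abs=1e-5)

    def test_identical_embeddings_log_n_minus_1(self):
        z = np.tile([1.0, 0.0], (3, 1))
        loss = cur.supcon_loss(z, [0, 0, 0], tau=0.5)
        assert loss.item() == pytest.approx(np.log(2.0), abs=1e-6)

    def test_no_positives_warns_and_returns_zero(self):
        z = np.eye(3)
        with pytest.warns(UserWarning, match="no positives"):
            loss = cur.supcon_loss(z, [0, 1, 2], tau=1.0)
        assert loss.item() == 0.0

    @pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (8, 2)])
    def test_enumeration_oracle_equality(self, n, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(n, 5))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        labels = rng.integers(0, 2, size=n)
        if len(set(labels.tolist())) == 1 or min(np.bincount(labels)) < 2:
            labels[: n // 2] = 0
            labels[n // 2 :] = 1
        ours = cur.supcon_loss(z, labels, tau=0.3).item()
        oracle = supcon_enumeration_oracle(z, labels, 0.3)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError):
            cur.supcon_loss(np.ones((1, 4)), [0], tau=1.0)

    def test_descends_on_separable_toy_problem(self):
        """Gradient steps on the projection shrink the contrastive loss."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 4)).astype(np.float32)
        labels = np.array([0] * 6 + [1] * 6)
        x[labels == 1] += 2.0
        w = ag.Parameter(rng.normal(0, 0.5, size=(4, 3)).astype(np.float32), tag="w")
        opt = ag.AdamW([w])

        def loss_t():
            z = ag.l2_normalize(Tensor(x) @ w, axis=-1)
            return cur.supcon_loss(z, labels, tau=0.2)

        first = loss_t().item()
        for _ in range(60):
            opt.zero_grad()
            l = loss_t()
            l.backward()
            opt.step(lr=0.03)
        assert loss_t().item() < first - 0.1


class TestSimpleLosses:
    def test_entropy_reg_values(self):
        assert cur.entropy_reg_loss(np.full(4, 0.25)).item() == pytest.approx(
            -np.log(4), abs=1e-6
        )
        assert cur.entropy_reg_loss(np.array([1.0, 0.0])).item() == pytest.approx(0.0, abs=1e-9)
        assert cur.entropy_reg_loss(np.array([0.5, 0.25, 0.25])).item() == pytest.approx(
            -1.03972, abs=1e-5
        )

    def test_phase0_total_arithmetic(self):
        assert cur.phase0_total(0.5, -1.0, 0.01) == pytest.approx(0.49)
        assert cur.phase0_total(0.7, -5.0, 0.0) == pytest.approx(0.7)
        with pytest.raises(ValueError):
            cur.phase0_total(0.5, -1.0, -0.1)

    @pytest.mark.parametrize(
        "probs,label,gamma,expected",
        [
            ([[0.0, 1.0]], 1, 2.0, 0.0),
            ([[0.5, 0.5]], 0, 0.0, np.log(2)),
            ([[0.1, 0.9]], 1, 2.0, 0.0010536),
        ],
    )
    def test_focal_closed_forms(self, probs, label, gamma, expected):
        cfg = cur.FocalConfig(gamma=gamma, alpha_t=(1.0, 1.0))
        loss = cur.focal_chunk_loss(np.array(probs), label, cfg)
        assert loss.item() == pytest.approx(expected, abs=1e-6)

    def test_focal_class_weighting(self):
        cfg = cur.FocalConfig(gamma=0.0, alpha_t=(2.0, 0.5))
        l0 = cur.focal_chunk_loss(np.array([[0.5, 0.5]]), 0, cfg).item()
        l1 = cur.focal_chunk_loss(np.array([[0.5, 0.5]]), 1, cfg).item()
        assert l0 == pytest.approx(4 * l1)

    def test_session_ce_values(self):
        assert cur.session_ce_loss(np.array([0.5, 0.5]), 0).item() == pytest.approx(
            np.log(2), abs=1e-6
        )
        assert cur.session_ce_loss(np.array([0.9, 0.1]), 0).item() == pytest.approx(
            0.10536, abs=1e-5
        )
        assert cur.session_ce_loss(np.array([0.0, 1.0]), 1).item() == pytest.approx(
            0.0, abs=1e-9
        )

    def test_session_ce_zero_probability_clamped(self):
        with pytest.warns(UserWarning, match="clamp"):
            loss = cur.session_ce_loss(np.array([0.0, 1.0]), 0)
        assert np.isfinite(loss.item())


class TestPhaseSchedule:
    def test_phase0_epoch10(self):
        cfg = cur.phase_schedule(10)
        assert cfg.phase == 0
        assert "projection" in cfg.trainable_modules
        assert "classifier" in cfg.frozen_modules
        assert cfg.active_losses == ("supcon", "entropy")
        assert cfg.base_lr == pytest.approx(3e-4)
        assert cfg.weight_decay == pytest.approx(1e-4)

    def test_phase1_epoch26_gate_unfrozen_no_session_ce(self):
        cfg = cur.phase_schedule(26)
        assert cfg.phase == 1
        assert "gate" in cfg.trainable_modules  # unfrozen from epoch 25
        assert "session_ce" not in cfg.active_losses
        assert "projection" in cfg.frozen_modules
        cfg24 = cur.phase_schedule(24)
        assert "gate" in cfg24.frozen_modules

    def test_phase2_epoch40_alpha_g_midpoint(self):
        cfg = cur.phase_schedule(40)
        assert cfg.phase == 2
        assert cfg.alpha_g == pytest.approx(1.65)
        assert cfg.lr_scales == {"scorer": 0.1}
        assert cfg.active_losses == ("session_ce",)

    def test_alpha_g_endpoints(self):
        assert cur.phase_schedule(30).alpha_g == pytest.approx(1.5)
        assert cur.phase_schedule(50).alpha_g == pytest.approx(1.8)

    def test_topk_annealing_endpoints(self):
        assert cur.phase_schedule(15).topk_ratio == pytest.approx(0.9)
        assert cur.phase_schedule(29).topk_ratio == pytest.approx(0.3)

    def test_one_phase_per_epoch_contiguous(self):
        phases = [cur.phase_schedule(e).phase for e in range(51)]
        assert phases == sorted(phases)
        assert phases.count(0) == 15 and phases.count(1) == 15 and phases.count(2) == 21

    def test_curriculum_variants(self):
        assert cur.phase_schedule(0, curriculum="direct").phase == 2
        assert cur.phase_schedule(0, curriculum="no-supcon").phase == 1
        assert cur.phase_schedule(20, curriculum="no-topk").topk_ratio == 1.0
        with pytest.raises(ValueError):
            cur.phase_epochs((5, 5, 5), "bogus")

    def test_cosine_decay_within_phase(self):
        lrs = [cur.phase_schedule(e).lr for e in range(15)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert lrs[0] == pytest.approx(3e-4)


class TestHandover:
    def test_identity_on_shared_weights(self):
        m = Model(seed=0)
        x = Tensor(np.random.default_rng(0).normal(size=256).astype(np.float32))
        before = m.classify(x).data.copy()
        n_before = m.n_parameters("training")
        cur.handover_classifier(m.state_copy(), m)
        np.testing.assert_array_equal(m.classify(x).data, before)
        assert m.n_parameters("training") == n_before

    def test_shape_mismatch_rejected(self):
        m = Model(seed=0)
        bad = m.state_copy()
        bad["clf.w1"] = bad["clf.w1"][:, :10]
        with pytest.raises(ValueError, match="mismatch"):
            cur.handover_classifier(bad, m)

    def test_missing_key_rejected(self):
        m = Model(seed=0)
        bad = m.state_copy()
        del bad["clf.w2"]
        with pytest.raises(ValueError, match="clf.w2"):
            cur.handover_classifier(bad, m)


@pytest.fixture(scope="module")
def smoke_records():
    manifest, waves, _ = bvpsynth.generate_dataset(
        20, duration_s=43.0, seed=13, event_count_range=(2, 2)
    )
    manifest = sessionio.split_manifest(manifest, seed=13)
    return [
        sessionio.SessionRecord(
            e["session_id"],
            waves[e["session_id"]],
            e["rating_arousal"],
            e["rating_valence"],
            e["split"],
        )
        for e in manifest
    ]


class TestRunCurriculum:
    def test_smoke_run_completes_and_reloads(self, smoke_records, tmp_path):
        result = cur.run_curriculum(
            smoke_records, "arousal", epochs=(2, 2, 2), seed=0, out_dir=tmp_path
        )
        assert len(result.log.records) == 6
        assert [r["phase"] for r in result.log.records] == [0, 0, 1, 1, 2, 2]
        # checkpoint reload reproduces validation metrics exactly
        reloaded = Model.load(tmp_path / "checkpoint.npz")
        chunks = sessionio.chunk_waveform(smoke_records[0].waveform).chunks.astype(
            np.float32
        )
        p1 = cur.predict_session(result.model, chunks, result.inference_alpha)[1]
        p2 = cur.predict_session(reloaded, chunks, result.inference_alpha)[1]
        np.testing.assert_array_equal(p1, p2)
        log_lines = (tmp_path / "log.jsonl").read_text().strip().split("\n")
        assert len(log_lines) == 6 and json.loads(log_lines[0])["epoch"] == 0

    def test_same_seed_reproduces_losses(self, smoke_records):
        a = cur.run_curriculum(smoke_records, "arousal", epochs=(1, 1, 1), seed=7)
        b = cur.run_curriculum(smoke_records, "arousal", epochs=(1, 1, 1), seed=7)
        assert [r["loss"] for r in a.log.records] == [r["loss"] for r in b.log.records]

    def test_invalid_target_rejected(self, smoke_records):
        with pytest.raises(ValueError):
            cur.run_curriculum(smoke_records, "mood", epochs=(1, 1, 1))

    def test_unsplit_manifest_rejected(self, smoke_records):
        records = [
            sessionio.SessionRecord(
                r.session_id, r.waveform, r.rating_arousal, r.rating_valence, "unassigned"
            )
            for r in smoke_records
        ]
        with pytest.raises(ValueError, match="split"):
            cur.run_curriculum(records, "arousal", epochs=(1, 1, 1))
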