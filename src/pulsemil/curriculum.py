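"""Three-phase curriculum training.

The model is trained from weak session-level labels in three phases that
move from representation learning to discrimination to exploitation:

* **Phase 0 — exploration** (default epochs 0–14): the encoder, scorer
  and projection head are trained with a supervised contrastive loss on
  per-chunk projections (chunks inherit their session's binary label)
  plus an entropy regulariser on the scorer's internal softmax attention
  that keeps early attention broad. lr 3e-4, weight decay 1e-4.
* **Phase 1 — chunk-level discrimination** (epochs 15–29): the
  projection head is frozen; the shared chunk/session classifier is
  trained with focal loss (gamma = 2) on only the Top-K chunks selected
  by the scorer's alpha-entmax attention, with the Top-K ratio annealed
  0.9 -> 0.3 across the phase. From two-thirds of the way through the
  phase the gate parameters are unfrozen in preparation, but the
  session loss is not yet part of the objective. lr 2e-4, wd 5e-4.
* **Phase 2 — session-level fine-tuning** (epochs >= 30): everything but
  the projection head is fine-tuned on session cross-entropy through
  gated pooling, with the scorer at a 10x reduced learning rate and the
  pooling entmax alpha_g annealed 1.5 -> 1.8 across the phase. lr 1e-4,
  wd 5e-4.

Optimisation is AdamW with a cosine-annealed learning rate restarting at
each phase boundary; batches hold complete sessions (default 8) and
attention is always normalised within a session, never across sessions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import sessionio
from .autograd import Tensor
from .network import Model, ModelConfig, canonical_config
from .sparsecore import LinearSchedule, schedule_value, topk_support

logger = logging.getLogger(__name__)

ALL_TAGS = frozenset({"mtde", "scorer", "gate", "classifier", "projection"})
CURRICULA = ("full", "no-topk", "no-aux", "no-supcon", "direct")


# ------------------------------------------------------------------- losses
@dataclass(frozen=True)
class FocalConfig:
    """Focal-loss settings: focusing parameter and per-class weights."""

    gamma: float = 2.0
    alpha_t: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if any(a <= 0 for a in self.alpha_t):
            raise ValueError("class weights must be positive")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def supcon_loss(z, labels, tau: float = 0.1) -> Tensor:
    """Supervised contrastive loss over unit-norm embeddings.

    Mean over anchors i with at least one positive of
    ``-(1/|P(i)|) sum_{p in P(i)} log[ exp(z_i.z_p/tau) /
    sum_{a != i} exp(z_i.z_a/tau) ]`` where positives share the anchor's
    label. Anchors without positives are skipped (warned if none remain).
    """
    z = _as_tensor(z)
    labels = np.asarray(labels)
    n = z.shape[0]
    if n < 2:
        raise ValueError("contrastive batch needs at least 2 embeddings")
    if labels.shape[0] != n:
        raise ValueError("labels and embeddings disagree in length")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    sim = (z @ ag.transpose(z)) * (1.0 / tau)
    eye = np.eye(n, dtype=bool)
    pos = (labels[:, None] == labels[None, :]) & ~eye
    counts = pos.sum(axis=1)
    anchors = counts > 0
    if not anchors.any():
        warnings.warn("no positives in contrastive batch; loss is 0")
        return Tensor(np.zeros(()))
    # stable log-sum-exp over A(i) = everyone but i (constants off-tape)
    m = np.max(np.where(eye, -np.inf, sim.data), axis=1, keepdims=True)
    e = ag.exp(sim - m) * (~eye).astype(float)
    log_denom = ag.log(e.sum(axis=1)) + m.reshape(n)
    log_prob = sim - log_denom.reshape(n, 1)
    per_anchor = (log_prob * pos.astype(float)).sum(axis=1) * (
        1.0 / np.maximum(counts, 1)
    )
    sel = np.flatnonzero(anchors)
    return -(per_anchor[sel].sum() * (1.0 / sel.size))


def entropy_reg_loss(p) -> Tensor:
    """Negative Shannon entropy of a simplex vector (minimise to spread)."""
    p = _as_tensor(p)
    return (p * ag.log(p + 1e-30)).sum()


def phase0_total(supcon, entropy_loss, lambda_entropy: float):
    """Phase-0 objective: supcon + lambda * entropy term."""
    if lambda_entropy < 0:
        raise ValueError("lambda_entropy must be >= 0")
    return supcon + lambda_entropy * entropy_loss


def focal_chunk_loss(chunk_probs, session_label: int, config: FocalConfig) -> Tensor:
    """Mean focal loss of selected chunks against the session's label."""
    p = _as_tensor(chunk_probs)
    if p.ndim != 2:
        raise ValueError("chunk_probs must be (n_chunks, n_classes)")
    a_t = config.alpha_t[session_label]
    pt = p[:, session_label]
    focus = (1.0 - pt) ** config.gamma if config.gamma != 0 else 1.0
    losses = -a_t * focus * ag.log(pt + 1e-12)
    return losses.mean()


def session_ce_loss(y_hat, y: int) -> Tensor:
    """Cross-entropy -log y_hat[y] with a 1e-12 clamp on zero probability."""
    p = _as_tensor(y_hat)
    if p.ndim != 1:
        raise ValueError("y_hat must be a probability vector")
    if not 0 <= y < p.shape[0]:
        raise ValueError(f"class index {y} out of range")
    if float(p.data[y]) < 1e-12:
        warnings.warn("zero predicted probability clamped at 1e-12")
    return -ag.log(p[y] + 1e-12)


# ------------------------------------------------------------------- phases
@dataclass(frozen=True)
class PhaseConfig:
    """Everything the trainer needs to know about one epoch."""

    phase: int
    epoch: int
    epoch_range: tuple[int, int]
    active_losses: tuple[str, ...]
    lambda_entropy: float
    lr: float
    base_lr: float
    weight_decay: float
    frozen_modules: frozenset[str]
    topk_ratio: float
    alpha_g: float
    scorer_alpha: float = 1.5
    lr_scales: dict = field(default_factory=dict)

    @property
    def trainable_modules(self) -> frozenset[str]:
        return ALL_TAGS - self.frozen_modules


def _cosine(base: float, rel: int, length: int) -> float:
    if length <= 1:
        return base
    return base * 0.5 * (1.0 + np.cos(np.pi * rel / length))


def phase_epochs(epochs: tuple[int, int, int], curriculum: str = "full") -> tuple[int, int, int]:
    """Per-phase epoch counts after applying a curriculum ablation."""
    if curriculum not in CURRICULA:
        raise ValueError(f"unknown curriculum {curriculum!r} (choose from {CURRICULA})")
    e0, e1, e2 = epochs
    if curriculum == "no-aux":
        e1 = 0
    elif curriculum == "no-supcon":
        e0 = 0
    elif curriculum == "direct":
        e0 = e1 = 0
    return e0, e1, e2


def phase_schedule(
    epoch: int,
    epochs: tuple[int, int, int] = (15, 15, 21),
    curriculum: str = "full",
    lambda_entropy: float = 0.01,
    topk_endpoints: tuple[float, float] = (0.9, 0.3),
    alpha_g_endpoints: tuple[float, float] = (1.5, 1.8),
    scorer_alpha: float = 1.5,
    lrs: tuple[float, float, float] = (3e-4, 2e-4, 1e-4),
    weight_decays: tuple[float, float, float] = (1e-4, 5e-4, 5e-4),
) -> PhaseConfig:
    """Resolve the phase configuration governing a given epoch.

    With the default epoch budget (15, 15, 21) this reproduces the
    canonical schedule: phase 0 on epochs 0-14, phase 1 on 15-29 with the
    Top-K ratio annealed 0.9 -> 0.3 and the gate unfrozen from epoch 25,
    phase 2 from epoch 30 with alpha_g annealed 1.5 (epoch 30) -> 1.8
    (epoch 50) and the scorer at a 10x reduced learning rate.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    e0, e1, e2 = phase_epochs(epochs, curriculum)
    total = e0 + e1 + e2
    if epoch >= total:
        raise ValueError(f"epoch {epoch} outside the {total}-epoch curriculum")
    b1, b2 = e0, e0 + e1  # phase boundaries

    topk_hi, topk_lo = topk_endpoints
    if curriculum == "no-topk":
        topk_hi = topk_lo = 1.0
    topk_ratio = (
        schedule_value(LinearSchedule(b1, b2 - 1, topk_hi, topk_lo), epoch)
        if e1 > 1 and topk_hi != topk_lo
        else topk_hi
    )
    ag_lo, ag_hi = alpha_g_endpoints
    alpha_g = (
        schedule_value(LinearSchedule(b2, b2 + e2 - 1, ag_lo, ag_hi), epoch)
        if e2 > 1
        else ag_lo
    )

    if epoch < b1:
        rel, length = epoch, e0
        frozen = frozenset({"gate", "classifier"})
        return PhaseConfig(
            phase=0,
            epoch=epoch,
            epoch_range=(0, b1),
            active_losses=("supcon", "entropy"),
            lambda_entropy=lambda_entropy,
            lr=_cosine(lrs[0], rel, length),
            base_lr=lrs[0],
            weight_decay=weight_decays[0],
            frozen_modules=frozen,
            topk_ratio=topk_hi,
            alpha_g=ag_lo,
            scorer_alpha=scorer_alpha,
        )
    if epoch < b2:
        rel, length = epoch - b1, e1
        gate_unfreeze = b1 + int(np.ceil(2.0 * e1 / 3.0))
        frozen = {"projection", "gate"}
        if epoch >= gate_unfreeze:
            frozen.discard("gate")  # unfrozen, but session CE not yet in the loss
        return PhaseConfig(
            phase=1,
            epoch=epoch,
            epoch_range=(b1, b2),
            active_losses=("focal",),
            lambda_entropy=0.0,
            lr=_cosine(lrs[1], rel, length),
            base_lr=lrs[1],
            weight_decay=weight_decays[1],
            frozen_modules=frozenset(frozen),
            topk_ratio=topk_ratio,
            alpha_g=ag_lo,
            scorer_alpha=scorer_alpha,
        )
    rel, length = epoch - b2, e2
    return PhaseConfig(
        phase=2,
        epoch=epoch,
        epoch_range=(b2, total),
        active_losses=("session_ce",),
        lambda_entropy=0.0,
        lr=_cosine(lrs[2], rel, length),
        base_lr=lrs[2],
        weight_decay=weight_decays[2],
        frozen_modules=frozenset({"projection"}),
        topk_ratio=topk_ratio,
        alpha_g=alpha_g,
        scorer_alpha=scorer_alpha,
        lr_scales={"scorer": 0.1},
    )


def handover_classifier(aux_state: dict[str, np.ndarray], model: Model) -> None:
    """Initialise the main classifier from the auxiliary chunk classifier.

    The two heads share one parameter set, so the handover is an identity
    operation; it is validated and logged rather than copied.
    """
    for name in ("clf.w1", "clf.b1", "clf.w2", "clf.b2"):
        if name not in aux_state:
            raise ValueError(f"auxiliary classifier state missing {name}")
        if aux_state[name].shape != model.params[name].data.shape:
            raise ValueError(
                f"classifier shape mismatch at {name}: "
                f"{aux_state[name].shape} vs {model.params[name].data.shape}"
            )
        model.params[name].data = aux_state[name].copy()
    logger.info("main classifier initialised from auxiliary head (shared weights)")


# ------------------------------------------------------------------ training
@dataclass
class TrainingLog:
    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r) + "\n")


@dataclass
class RunResult:
    model: Model
    log: TrainingLog
    inference_alpha: float
    best_val_accuracy: float
    focal: FocalConfig
    target: str


def _session_arrays(records, target: str):
    """Chunk every session once; returns (ids by split, chunks, labels)."""
    by_split: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    chunks: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    for rec in records:
        cs = sessionio.chunk_waveform(rec.waveform, session_id=rec.session_id)
        chunks[rec.session_id] = cs.chunks.astype(np.float32)
        labels[rec.session_id] = 1 if rec.label(target) == "high" else 0
        if rec.split in by_split:
            by_split[rec.split].append(rec.session_id)
    if not by_split["train"]:
        raise ValueError("no training sessions in manifest (run the splitter first)")
    return by_split, chunks, labels


def _mean(terms: list[Tensor]) -> Tensor:
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def predict_session(
    model: Model, chunks: np.ndarray, alpha: float, mode: str | None = None
):
    """Inference path: encode -> score -> entmax -> pool -> classify.

    Returns (predicted class, probability vector, attention weights).
    """
    with ag.no_grad():
        h = model.encode(chunks)
        scores = model.score(h, training=False)
        att = ag.entmax(scores, alpha) if chunks.shape[0] > 1 else Tensor(np.ones(1))
        pooled = model.pool(h, att, mode)
        probs = model.classify(pooled).data
    return int(np.argmax(probs)), probs, att.data


def _accuracy(model, ids, chunks, labels, alpha, mode=None) -> float:
    if not ids:
        return float("nan")
    correct = sum(
        predict_session(model, chunks[sid], alpha, mode)[0] == labels[sid] for sid in ids
    )
    return correct / len(ids)


def run_curriculum(
    dataset,
    target: str = "arousal",
    config: ModelConfig | None = None,
    epochs: tuple[int, int, int] = (15, 15, 21),
    batch_sessions: int = 8,
    seed: int = 0,
    curriculum: str = "full",
    out_dir: str | Path | None = None,
    lambda_entropy: float = 0.01,
    tau: float = 0.1,
    max_supcon_chunks: int = 32,
    scorer_alpha: float = 1.5,
) -> RunResult:
    """Train a model through the three-phase curriculum.

    ``dataset`` is a manifest path or a list of
    :class:`~pulsemil.sessionio.SessionRecord` with split tags already
    assigned. One binary target (arousal or valence) is trained per call.
    Fully deterministic given ``seed``. Returns the best-validation model
    (restored) together with the per-epoch log.
    """
    if target not in ("arousal", "valence"):
        raise ValueError("target must be 'arousal' or 'valence'")
    records = (
        sessionio.load_dataset(dataset)
        if isinstance(dataset, (str, Path))
        else dataset
    )
    by_split, chunks, labels = _session_arrays(records, target)
    train_ids = by_split["train"]
    val_ids = by_split["val"] or train_ids

    counts = np.bincount([labels[s] for s in train_ids], minlength=2).astype(float)
    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    alpha_t = inv / inv[counts > 0].mean() if (counts > 0).any() else np.ones(2)
    focal = FocalConfig(gamma=2.0, alpha_t=tuple(alpha_t))

    config = config or canonical_config()
    rng = np.random.default_rng(seed)
    model = Model(config, seed=int(rng.integers(0, 2**31 - 1)))
    opt = ag.AdamW(model.parameters())
    log = TrainingLog()

    e0, e1, e2 = phase_epochs(epochs, curriculum)
    total_epochs = e0 + e1 + e2
    best_state = model.state_copy()
    best_val = -1.0
    best_alpha = scorer_alpha
    handed_over = False

    for epoch in range(total_epochs):
        cfg = phase_schedule(
            epoch,
            epochs,
            curriculum,
            lambda_entropy=lambda_entropy,
            scorer_alpha=scorer_alpha,
        )
        if cfg.phase == 2 and not handed_over:
            handover_classifier(model.state_copy(), model)
            handed_over = True
        opt.trainable_tags = set(cfg.trainable_modules)
        opt.lr_scales = dict(cfg.lr_scales)
        order = list(train_ids)
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), batch_sessions):
            batch = order[start : start + batch_sessions]
            loss = _batch_loss(model, batch, chunks, labels, cfg, focal, tau, max_supcon_chunks, rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch} (phase {cfg.phase}): {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(cfg.lr, cfg.weight_decay)
            epoch_losses.append(float(loss.data))
        eval_alpha = cfg.alpha_g if cfg.phase == 2 else cfg.scorer_alpha
        val_acc = _accuracy(model, val_ids, chunks, labels, eval_alpha)
        log.append(
            epoch=epoch,
            phase=cfg.phase,
            loss=float(np.mean(epoch_losses)),
            lr=cfg.lr,
            topk_ratio=cfg.topk_ratio,
            alpha_g=cfg.alpha_g,
            val_accuracy=val_acc,
            seed=seed,
        )
        if val_acc >= best_val:
            best_val = val_acc
            best_state = model.state_copy()
            best_alpha = eval_alpha

    model.load_state(best_state)
    result = RunResult(
        model=model,
        log=log,
        inference_alpha=best_alpha,
        best_val_accuracy=best_val,
        focal=focal,
        target=target,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "checkpoint.npz")
        log.save(out / "log.jsonl")
        (out / "run.json").write_text(
            json.dumps(
                {
                    "target": target,
                    "seed": seed,
                    "curriculum": curriculum,
                    "epochs": list(epochs),
                    "inference_alpha": best_alpha,
                    "best_val_accuracy": best_val,
                    "config": config.to_dict(),
                },
                indent=1,
            )
        )
    return result


def _batch_loss(model, batch, chunks, labels, cfg, focal, tau, max_supcon_chunks, rng):
    x = np.concatenate([chunks[sid] for sid in batch], axis=0)
    h = model.encode(x)
    offsets = np.cumsum([0] + [chunks[sid].shape[0] for sid in batch])
    terms: list[Tensor] = []
    if cfg.phase == 0:
        sel_idx, sel_labels = [], []
        ent_terms = []
        for i, sid in enumerate(batch):
            a, b = offsets[i], offsets[i + 1]
            idx = np.arange(a, b)
            if idx.size > max_supcon_chunks:
                idx = np.sort(rng.choice(idx, size=max_supcon_chunks, replace=False))
            sel_idx.append(idx)
            sel_labels.extend([labels[sid]] * idx.size)
            scores = model.score(h[a:b], training=True)
            if b - a > 1:
                ent_terms.append(entropy_reg_loss(ag.softmax(scores)))
        z = model.project(h[np.concatenate(sel_idx)])
        sup = supcon_loss(z, np.asarray(sel_labels), tau)
        ent = _mean(ent_terms) if ent_terms else Tensor(np.zeros(()))
        return phase0_total(sup, ent, cfg.lambda_entropy)
    for i, sid in enumerate(batch):
        a, b = offsets[i], offsets[i + 1]
        hs = h[a:b]
        scores = model.score(hs, training=True)
        if cfg.phase == 1:
            att = ag.entmax(scores, cfg.scorer_alpha) if b - a > 1 else Tensor(np.ones(1))
            sel = topk_support(att.data, cfg.topk_ratio)
            probs = model.classify(hs[sel])
            terms.append(focal_chunk_loss(probs, labels[sid], focal))
        else:
            att = ag.entmax(scores, cfg.alpha_g) if b - a > 1 else Tensor(np.ones(1))
            pooled = model.pool(hs, att)
            terms.append(session_ce_loss(model.classify(pooled), labels[sid]))
    return _mean(terms)
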