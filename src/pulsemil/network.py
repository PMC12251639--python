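"""The temporal emotion-recognition model.

Architecture, per 128-sample BVP chunk:

* **MTDE** (multi-scale temporal dynamics encoder): a SlimStem of two
  k=3 convolutions (1->16->16), followed by three parallel dilated
  branches whose receptive fields are aligned to the HRV timescales —
  short (~0.2 s, beat-to-beat / HF-like), medium (~2.2 s, LF-like) and
  long (~4.3 s, VLF-like) — concatenated and fused by a 1x1 convolution
  to 256 channels, then reduced over the 128 time steps by softmax
  temporal attention pooling to one 256-d chunk embedding h_i. All
  convolutions are stride 1, same-length zero padded, GELU activated,
  with no normalisation layers.
* **AttnScorer**: a 2-layer MLP (256 -> 81 -> 1, GELU) scoring each
  chunk, followed by sigma-gamma scaling (running-std gain control with
  a learnable gain); downstream the scores become a distribution over a
  session's chunks via softmax or alpha-entmax.
* **Gated pooling**: h_pooled = sum_i alpha_i * (g_i ⊙ h_i) with
  per-chunk gates g_i = sigmoid(affine(h_i)) in (0,1)^256. Ablation
  modes force g_i = 1 ("attention") or additionally alpha_i = 1/T
  ("average").
* **Classifier**: 256 -> 47 -> 2 (GELU, softmax). One parameter set
  serves both as the chunk-level auxiliary classifier and the session
  classifier, which is what makes the train/inference parameter gap
  exactly the 32,896 parameters of the projection head.
* **Projection head** (training only): 256 -> 128 affine followed by L2
  normalisation, for the supervised contrastive loss.

With the canonical configuration the model counts exactly 164,996
trainable parameters at inference and 197,892 including the projection
head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

EMBED_DIM = 256
CHUNK_LEN = 128
FS = 30.0

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ConvLayerSpec:
    in_channels: int
    out_channels: int
    kernel: int
    dilation: int = 1
    bias: bool = True

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")

    @property
    def n_params(self) -> int:
        return self.kernel * self.in_channels * self.out_channels + (
            self.out_channels if self.bias else 0
        )


# canonical layer stacks; reverse-engineered to satisfy both the printed
# receptive fields (0.2 / 2.2 / 4.3 s) and the printed parameter budgets
STEM = (ConvLayerSpec(1, 16, 3, 1), ConvLayerSpec(16, 16, 3, 1))
BRANCH_SHORT = (ConvLayerSpec(16, 64, 2, 1),)
BRANCH_MEDIUM = (ConvLayerSpec(16, 32, 3, 15), ConvLayerSpec(32, 64, 2, 31))
BRANCH_LONG = (ConvLayerSpec(16, 32, 3, 31), ConvLayerSpec(32, 64, 3, 31))
BRANCH_MEDIUM2 = (ConvLayerSpec(16, 32, 3, 8), ConvLayerSpec(32, 64, 2, 15))

POOLING_MODES = ("gated", "attention", "average")


def _branches_for(n: int) -> dict[str, tuple[ConvLayerSpec, ...]]:
    if n == 1:
        return {"long": BRANCH_LONG}
    if n == 2:
        return {"short": BRANCH_SHORT, "long": BRANCH_LONG}
    if n == 3:
        return {"short": BRANCH_SHORT, "medium": BRANCH_MEDIUM, "long": BRANCH_LONG}
    if n == 4:
        return {
            "short": BRANCH_SHORT,
            "medium": BRANCH_MEDIUM,
            "medium2": BRANCH_MEDIUM2,
            "long": BRANCH_LONG,
        }
    raise ValueError(f"branch count must be 1-4, got {n}")


@dataclass(frozen=True)
class ModelConfig:
    stem: tuple[ConvLayerSpec, ...] = STEM
    branches: tuple[tuple[str, tuple[ConvLayerSpec, ...]], ...] = tuple(
        _branches_for(3).items()
    )
    embed_dim: int = EMBED_DIM
    scorer_hidden: int = 81
    classifier_hidden: int = 47
    projection_dim: int = 128
    n_classes: int = 2
    pooling_mode: str = "gated"

    def __post_init__(self) -> None:
        if self.pooling_mode not in POOLING_MODES:
            raise ValueError(f"pooling_mode must be one of {POOLING_MODES}")

    @property
    def fusion(self) -> ConvLayerSpec:
        cat = sum(b[-1].out_channels for _, b in self.branches)
        return ConvLayerSpec(cat, self.embed_dim, 1, 1)

    def to_dict(self) -> dict:
        return {
            "stem": [vars(l) | {} for l in self.stem],
            "branches": {name: [dict(in_channels=l.in_channels, out_channels=l.out_channels, kernel=l.kernel, dilation=l.dilation, bias=l.bias) for l in layers] for name, layers in self.branches},
            "embed_dim": self.embed_dim,
            "scorer_hidden": self.scorer_hidden,
            "classifier_hidden": self.classifier_hidden,
            "projection_dim": self.projection_dim,
            "n_classes": self.n_classes,
            "pooling_mode": self.pooling_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        mk = lambda l: ConvLayerSpec(**{k: l[k] for k in ("in_channels", "out_channels", "kernel", "dilation", "bias")})
        return cls(
            stem=tuple(mk(l) for l in d["stem"]),
            branches=tuple((n, tuple(mk(l) for l in ls)) for n, ls in d["branches"].items()),
            embed_dim=d["embed_dim"],
            scorer_hidden=d["scorer_hidden"],
            classifier_hidden=d["classifier_hidden"],
            projection_dim=d["projection_dim"],
            n_classes=d["n_classes"],
            pooling_mode=d["pooling_mode"],
        )


def canonical_config(pooling_mode: str = "gated", n_branches: int = 3) -> ModelConfig:
    """The default configuration (and its ablation variants)."""
    return ModelConfig(
        branches=tuple(_branches_for(n_branches).items()), pooling_mode=pooling_mode
    )


def receptive_field(layers: list[ConvLayerSpec] | tuple) -> tuple[int, float]:
    """(frames, seconds at 30 Hz) spanned by a stride-1 convolution stack.

    frames = 1 + sum (kernel - 1) * dilation.
    """
    layers = tuple(layers)
    if not layers:
        raise ValueError("empty layer stack")
    frames = 1 + sum((l.kernel - 1) * l.dilation for l in layers)
    return frames, frames / FS


def count_trainable(config: ModelConfig, scope: str = "inference") -> int:
    """Exact trainable-parameter count of a configuration.

    ``inference`` covers MTDE + AttnScorer (incl. the sigma-gamma gain) +
    gate + classifier; ``training`` adds the contrastive projection head.
    """
    if scope not in ("inference", "training"):
        raise ValueError(f"scope must be 'inference' or 'training', got {scope!r}")
    d = config.embed_dim
    n = sum(l.n_params for l in config.stem)
    n += sum(l.n_params for _, branch in config.branches for l in branch)
    n += config.fusion.n_params
    n += d + 1  # intra-chunk softmax pooling scorer (affine d -> 1)
    n += d * config.scorer_hidden + config.scorer_hidden  # scorer layer 1
    n += config.scorer_hidden + 1  # scorer layer 2
    n += 1  # sigma-gamma gain
    n += d * d + d  # gate affine
    n += d * config.classifier_hidden + config.classifier_hidden
    n += config.classifier_hidden * config.n_classes + config.n_classes
    if scope == "training":
        n += d * config.projection_dim + config.projection_dim
    return n


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Model:
    """Trainable model instance; parameters are autograd tensors.

    Module tags (used by the curriculum for freezing and learning-rate
    scaling): ``mtde``, ``scorer``, ``gate``, ``classifier``,
    ``projection``.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or canonical_config()
        rng = np.random.default_rng(seed)
        self.params: dict[str, Parameter] = {}
        d = self.config.embed_dim

        def conv_params(prefix: str, layer: ConvLayerSpec, tag: str):
            fan = layer.kernel * layer.in_channels
            self._add(
                f"{prefix}.w",
                _he_init(rng, (layer.kernel, layer.in_channels, layer.out_channels), fan),
                tag,
            )
            self._add(f"{prefix}.b", np.zeros(layer.out_channels, dtype=np.float32), tag)

        for i, l in enumerate(self.config.stem):
            conv_params(f"stem.{i}", l, "mtde")
        for name, branch in self.config.branches:
            for i, l in enumerate(branch):
                conv_params(f"branch.{name}.{i}", l, "mtde")
        conv_params("fusion", self.config.fusion, "mtde")
        self._add("pool_scorer.w", _he_init(rng, (d, 1), d), "mtde")
        self._add("pool_scorer.b", np.zeros(1, dtype=np.float32), "mtde")

        h = self.config.scorer_hidden
        self._add("scorer.w1", _he_init(rng, (d, h), d), "scorer")
        self._add("scorer.b1", np.zeros(h, dtype=np.float32), "scorer")
        self._add("scorer.w2", _he_init(rng, (h, 1), h), "scorer")
        self._add("scorer.b2", np.zeros(1, dtype=np.float32), "scorer")
        self._add("scorer.gamma", np.ones((), dtype=np.float32), "scorer")

        # gate bias starts positive so gates open near 1: at the phase-1 ->
        # phase-2 handover the pooled vector then matches the scale of the
        # chunk embeddings the shared classifier was trained on
        self._add("gate.w", _he_init(rng, (d, d), d), "gate")
        self._add("gate.b", np.full(d, 2.0, dtype=np.float32), "gate")

        c = self.config.classifier_hidden
        self._add("clf.w1", _he_init(rng, (d, c), d), "classifier")
        self._add("clf.b1", np.zeros(c, dtype=np.float32), "classifier")
        self._add("clf.w2", _he_init(rng, (c, self.config.n_classes), c), "classifier")
        self._add("clf.b2", np.zeros(self.config.n_classes, dtype=np.float32), "classifier")

        p = self.config.projection_dim
        self._add("proj.w", _he_init(rng, (d, p), d), "projection")
        self._add("proj.b", np.zeros(p, dtype=np.float32), "projection")

        # sigma-gamma running std: a buffer, not a parameter
        self.scale_sigma: float = 1.0
        self.scale_momentum: float = 0.99
        self.scale_epsilon: float = 1e-5

    def _add(self, name: str, data: np.ndarray, tag: str) -> None:
        self.params[name] = Parameter(data, name=name, tag=tag)

    # ---------------------------------------------------------------- pieces
    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def n_parameters(self, scope: str = "inference") -> int:
        if scope not in ("inference", "training"):
            raise ValueError("scope must be 'inference' or 'training'")
        skip = {"projection"} if scope == "inference" else set()
        return sum(p.data.size for p in self.params.values() if p.tag not in skip)

    def encode(self, chunks: np.ndarray | Tensor) -> Tensor:
        """Encode (N, 128) chunks to (N, 256) embeddings h_i."""
        x = chunks if isinstance(chunks, Tensor) else Tensor(np.asarray(chunks, dtype=np.float32))
        if x.ndim != 2 or x.shape[1] != CHUNK_LEN:
            raise ValueError(f"chunks must be (N, {CHUNK_LEN}), got {x.shape}")
        h = x.reshape(x.shape[0], CHUNK_LEN, 1)
        for i, l in enumerate(self.config.stem):
            h = ag.gelu(
                ag.conv1d_same(h, self.params[f"stem.{i}.w"], self.params[f"stem.{i}.b"], l.dilation)
            )
        outs = []
        for name, branch in self.config.branches:
            y = h
            for i, l in enumerate(branch):
                y = ag.gelu(
                    ag.conv1d_same(
                        y,
                        self.params[f"branch.{name}.{i}.w"],
                        self.params[f"branch.{name}.{i}.b"],
                        l.dilation,
                    )
                )
            outs.append(y)
        cat = ag.concatenate(outs, axis=2) if len(outs) > 1 else outs[0]
        fused = ag.gelu(
            ag.conv1d_same(cat, self.params["fusion.w"], self.params["fusion.b"], 1)
        )  # (N, 128, 256)
        # intra-chunk softmax temporal attention pooling
        n = fused.shape[0]
        flat = fused.reshape(n * CHUNK_LEN, self.config.embed_dim)
        scores = (flat @ self.params["pool_scorer.w"] + self.params["pool_scorer.b"]).reshape(
            n, CHUNK_LEN
        )
        w = ag.softmax(scores, axis=-1).reshape(n, CHUNK_LEN, 1)
        return (fused * w).sum(axis=1)

    def raw_scores(self, h: Tensor) -> Tensor:
        """Unscaled AttnScorer outputs, one scalar per chunk."""
        z = ag.gelu(h @ self.params["scorer.w1"] + self.params["scorer.b1"])
        return (z @ self.params["scorer.w2"] + self.params["scorer.b2"]).reshape(h.shape[0])

    def score(self, h: Tensor, training: bool = False) -> Tensor:
        """Sigma-gamma-scaled attention scores for one session's chunks.

        In training mode the scores of this session update the running
        std estimate (after scaling, so a call is side-effect-ordered the
        same way as the functional primitive in :mod:`sparsecore`).
        """
        raw = self.raw_scores(h)
        inv = 1.0 / (self.scale_sigma + self.scale_epsilon)
        scaled = raw * (self.params["scorer.gamma"] * inv)
        if training and raw.shape[0] >= 2:
            sd = float(np.std(raw.data))
            if sd > 0.0:
                self.scale_sigma = (
                    self.scale_momentum * self.scale_sigma
                    + (1.0 - self.scale_momentum) * sd
                )
        return scaled

    def gates(self, h: Tensor) -> Tensor:
        return ag.sigmoid(h @ self.params["gate.w"] + self.params["gate.b"])

    def pool(self, h: Tensor, attention: Tensor, mode: str | None = None) -> Tensor:
        """Gated temporal pooling: h_pooled = sum_i alpha_i * (g_i ⊙ h_i)."""
        mode = mode or self.config.pooling_mode
        if mode not in POOLING_MODES:
            raise ValueError(f"unknown pooling mode {mode!r}")
        t = h.shape[0]
        if attention.shape[0] != t:
            raise ValueError("attention and embeddings disagree on chunk count")
        if mode == "average":
            alpha = Tensor(np.full(t, 1.0 / t, dtype=np.float32))
        else:
            alpha = attention
        if mode == "gated":
            g = self.gates(h)
            weighted = h * g
        else:
            weighted = h
        return (weighted * alpha.reshape(t, 1)).sum(axis=0)

    def classify(self, x: Tensor) -> Tensor:
        """Class probabilities; shared aux/main head, accepts (..., 256)."""
        if x.shape[-1] != self.config.embed_dim:
            raise ValueError(f"classifier expects {self.config.embed_dim}-d input")
        single = x.ndim == 1
        if single:
            x = x.reshape(1, self.config.embed_dim)
        z = ag.gelu(x @ self.params["clf.w1"] + self.params["clf.b1"])
        logits = z @ self.params["clf.w2"] + self.params["clf.b2"]
        p = ag.softmax(logits, axis=-1)
        return p.reshape(self.config.n_classes) if single else p

    def project(self, h: Tensor) -> Tensor:
        """Contrastive projection: affine to 128-d then L2 normalisation."""
        if h.shape[-1] != self.config.embed_dim:
            raise ValueError(f"projection expects {self.config.embed_dim}-d input")
        return ag.l2_normalize(h @ self.params["proj.w"] + self.params["proj.b"], axis=-1)

    # ------------------------------------------------------------ checkpoint
    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: npz of parameters + JSON sidecar config."""
        path = Path(path)
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(path, **arrays, __scale_sigma=np.float64(self.scale_sigma))
        meta = {"version": CHECKPOINT_VERSION, "config": self.config.to_dict()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        model = cls(ModelConfig.from_dict(meta["config"]))
        with np.load(path) as data:
            for name, p in model.params.items():
                p.data = data[name].astype(np.float32)
            model.scale_sigma = float(data["__scale_sigma"])
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.params.items():
            p.data = state[name].copy()


def describe(config: ModelConfig | None = None) -> str:
    """Human-readable per-module parameter accounting."""
    config = config or canonical_config()
    lines = []
    stem_n = sum(l.n_params for l in config.stem)
    lines.append(f"stem: {stem_n}")
    for name, branch in config.branches:
        frames, secs = receptive_field(config.stem + branch)
        n = sum(l.n_params for l in branch)
        lines.append(f"branch {name}: {n} (RF {frames} frames = {secs:.1f} s)")
    lines.append(f"fusion: {config.fusion.n_params}")
    lines.append(f"intra-chunk pool scorer: {config.embed_dim + 1}")
    d, h, c = config.embed_dim, config.scorer_hidden, config.classifier_hidden
    lines.append(f"attn scorer (incl. gain): {d * h + h + h + 1 + 1}")
    lines.append(f"gate: {d * d + d}")
    lines.append(f"classifier: {d * c + c + c * config.n_classes + config.n_classes}")
    lines.append(f"projection head: {d * config.projection_dim + config.projection_dim}")
    lines.append(f"total (inference): {count_trainable(config, 'inference')}")
    lines.append(f"total (training): {count_trainable(config, 'training')}")
    return "\n".join(lines)
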