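"""Stage A detection network: hourglass encoder-decoder with configurable
parameter-sharing topology.

Three topologies are supported:

* ``single_task`` -- one fully independent encoder-decoder tower per task
  (no parameter sharing at all; the single-task learning baseline),
* ``multi_head`` -- one shared encoder *and* decoder; only lightweight 1x1
  prediction heads are task-specific,
* ``multi_decoder`` -- a shared encoder, with a task-specific decoder and
  head per task.

Every convolution block is a stack of residual pre-activation bottleneck
units and the channel count is constant across all scales of the hourglass.
Segmentation heads squash their output through a per-channel sigmoid
(multi-label, overlap-aware); keypoint/line heads are linear regression
heads whose decoded values are clamped to [0, 1] only at decoding time.

For GradNorm task weighting the model reports, per task, the gradient norm
of the weighted task loss with respect to a designated shared layer: the
last shared convolution before the task-specific part (after the decoder
for ``multi_head``, after the encoder bottleneck for ``multi_decoder``).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .nn import BatchNorm2d, Bottleneck, Conv2d, Decoder, Encoder, Module, ReLU, Sigmoid


class TaskKind(str, Enum):
    segmentation = "segmentation"
    keypoint = "keypoint"
    line = "line"


@dataclass(frozen=True)
class TaskSpec:
    name: str
    kind: TaskKind
    n_channels: int
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("task needs n_channels >= 1")
        if self.channel_labels and len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")


class Topology(str, Enum):
    single_task = "single_task"
    multi_head = "multi_head"
    multi_decoder = "multi_decoder"


@dataclass(frozen=True)
class ModelConfig:
    tasks: tuple[TaskSpec, ...]
    topology: Topology = Topology.multi_head
    n_features: int = 128
    depth: int = 4
    input_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "topology", Topology(self.topology))
        tasks = tuple(self.tasks)
        names = [t.name for t in tasks]
        if len(set(names)) != len(names):
            raise ValueError("task names must be unique")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )
        object.__setattr__(self, "tasks", tasks)


class _Head(Module):
    """Task-specific prediction head: one 3x3 mixing conv (BN, ReLU) and a
    1x1 projection to the task's channels. Kept deliberately small next to
    the trunk, but deep enough to separate the task's output channels from
    the shared representation."""

    def __init__(self, n_features: int, task: TaskSpec, rng: np.random.Generator) -> None:
        self.mix = Conv2d(n_features, n_features, 3, rng)
        self.bn = BatchNorm2d(n_features)
        self.relu = ReLU()
        self.conv = Conv2d(n_features, task.n_channels, 1, rng)
        self.sigmoid = Sigmoid() if task.kind == TaskKind.segmentation else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv.forward(self.relu.forward(self.bn.forward(self.mix.forward(x))))
        return self.sigmoid.forward(y) if self.sigmoid is not None else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.sigmoid is not None:
            dy = self.sigmoid.backward(dy)
        return self.mix.backward(self.bn.backward(self.relu.backward(self.conv.backward(dy))))


class _SharedTail(Module):
    """Last shared block: 3x3 conv (the GradNorm reference layer), BN, ReLU."""

    def __init__(self, n_features: int, rng: np.random.Generator) -> None:
        self.conv = Conv2d(n_features, n_features, 3, rng)
        self.bn = BatchNorm2d(n_features)
        self.relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class MultiTaskModel(Module):
    """Hourglass detection network; built via :func:`build_model`."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        t = config.topology
        f, d = config.n_features, config.depth
        self.heads = [_Head(f, task, rng) for task in config.tasks]
        if t == Topology.single_task:
            self.encoders = [Encoder(1, f, d, rng) for _ in config.tasks]
            self.decoders = [Decoder(f, d, rng) for _ in config.tasks]
            self.tails = [_SharedTail(f, rng) for _ in config.tasks]
        elif t == Topology.multi_head:
            self.encoders = [Encoder(1, f, d, rng)]
            self.decoders = [Decoder(f, d, rng)]
            self.tails = [_SharedTail(f, rng)]
        elif t == Topology.multi_decoder:
            self.encoders = [Encoder(1, f, d, rng)]
            self.tails = [_SharedTail(f, rng)]  # applied at the bottleneck
            self.decoders = [Decoder(f, d, rng) for _ in config.tasks]
        self._cache: dict = {}

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Batched forward pass; ``x`` is (N, 1, S, S)."""
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != s or x.shape[3] != s:
            raise ValueError(f"expected input of shape (N, 1, {s}, {s}), got {x.shape}")
        t = self.config.topology
        outs: dict[str, np.ndarray] = {}
        if t == Topology.single_task:
            for enc, dec, tail, head, task in zip(
                self.encoders, self.decoders, self.tails, self.heads, self.config.tasks
            ):
                bottom, skips = enc.forward(x)
                outs[task.name] = head.forward(tail.forward(dec.forward(bottom, skips)))
        elif t == Topology.multi_head:
            bottom, skips = self.encoders[0].forward(x)
            feat = self.tails[0].forward(self.decoders[0].forward(bottom, skips))
            for head, task in zip(self.heads, self.config.tasks):
                outs[task.name] = head.forward(feat)
        else:  # multi_decoder
            bottom, skips = self.encoders[0].forward(x)
            shared_bottom = self.tails[0].forward(bottom)
            for dec, head, task in zip(self.decoders, self.heads, self.config.tasks):
                outs[task.name] = head.forward(dec.forward(shared_bottom, skips))
        return outs

    # -- backward ---------------------------------------------------------

    def backward(
        self, d_outs: dict[str, np.ndarray], collect_gradnorm: bool = False
    ) -> Optional[dict[str, float]]:
        """Backpropagate per-task output gradients and accumulate parameter
        gradients. When ``collect_gradnorm`` is set, additionally return the
        L2 norm of each task's gradient contribution at the designated shared
        layer."""
        t = self.config.topology
        norms: dict[str, float] = {}
        if t == Topology.single_task:
            for enc, dec, tail, head, task in zip(
                self.encoders, self.decoders, self.tails, self.heads, self.config.tasks
            ):
                before = tail.conv.W.grad.copy() if collect_gradnorm else None
                dfeat = tail.backward(head.backward(d_outs[task.name]))
                if collect_gradnorm:
                    norms[task.name] = float(np.linalg.norm(tail.conv.W.grad - before))
                dbottom, dskips = dec.backward(dfeat)
                enc.backward(dbottom, dskips)
        elif t == Topology.multi_head:
            tail = self.tails[0]
            dfeat_total = None
            for head, task in zip(self.heads, self.config.tasks):
                before = tail.conv.W.grad.copy() if collect_gradnorm else None
                dfeat = tail.backward(head.backward(d_outs[task.name]))
                if collect_gradnorm:
                    norms[task.name] = float(np.linalg.norm(tail.conv.W.grad - before))
                dfeat_total = dfeat if dfeat_total is None else dfeat_total + dfeat
            dbottom, dskips = self.decoders[0].backward(dfeat_total)
            self.encoders[0].backward(dbottom, dskips)
        else:  # multi_decoder
            tail = self.tails[0]
            dbottom_total = None
            dskips_total: list[np.ndarray] | None = None
            for dec, head, task in zip(self.decoders, self.heads, self.config.tasks):
                dfeat = head.backward(d_outs[task.name])
                dsb, dskips = dec.backward(dfeat)
                before = tail.conv.W.grad.copy() if collect_gradnorm else None
                dbottom = tail.backward(dsb)
                if collect_gradnorm:
                    norms[task.name] = float(np.linalg.norm(tail.conv.W.grad - before))
                dbottom_total = dbottom if dbottom_total is None else dbottom_total + dbottom
                if dskips_total is None:
                    dskips_total = dskips
                else:
                    dskips_total = [a + b for a, b in zip(dskips_total, dskips)]
            self.encoders[0].backward(dbottom_total, dskips_total)
        return norms if collect_gradnorm else None

    # -- inference --------------------------------------------------------

    def infer(self, image: np.ndarray) -> dict[str, np.ndarray]:
        """Run a single preprocessed image (S, S) in [0, 1]; returns per-task
        raw output grids of shape (n_channels, S, S)."""
        s = self.config.input_size
        image = np.asarray(image, dtype=float)
        if image.shape != (s, s):
            raise ValueError(f"expected ({s}, {s}) input, got {image.shape}")
        self.set_train(False)
        outs = self.forward(image[None, None])
        return {name: out[0] for name, out in outs.items()}

    # -- checkpointing ----------------------------------------------------

    def save(self, path) -> None:
        cfg = {
            "topology": self.config.topology.value,
            "n_features": self.config.n_features,
            "depth": self.config.depth,
            "input_size": self.config.input_size,
            "seed": self.config.seed,
            "tasks": [
                {
                    "name": t.name,
                    "kind": t.kind.value,
                    "n_channels": t.n_channels,
                    "channel_labels": list(t.channel_labels),
                }
                for t in self.config.tasks
            ],
        }
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        bn_state = {}
        for i, m in enumerate(mod for mod in self.modules() if isinstance(mod, BatchNorm2d)):
            bn_state[f"bn_mean_{i}"] = m.running_mean
            bn_state[f"bn_var_{i}"] = m.running_var
        np.savez(path, config=json.dumps(cfg), **arrays, **bn_state)

    @classmethod
    def load(cls, path) -> "MultiTaskModel":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["config"]))
            tasks = tuple(
                TaskSpec(
                    name=t["name"],
                    kind=TaskKind(t["kind"]),
                    n_channels=t["n_channels"],
                    channel_labels=tuple(t["channel_labels"]),
                )
                for t in cfg["tasks"]
            )
            config = ModelConfig(
                tasks=tasks,
                topology=Topology(cfg["topology"]),
                n_features=cfg["n_features"],
                depth=cfg["depth"],
                input_size=cfg["input_size"],
                seed=cfg["seed"],
            )
            model = cls(config)
            arrays = [data[f"param_{i}"] for i in range(sum(1 for _ in model.parameters()))]
            model.load_state_arrays(arrays)
            for i, m in enumerate(mod for mod in model.modules() if isinstance(mod, BatchNorm2d)):
                m.running_mean = data[f"bn_mean_{i}"].copy()
                m.running_var = data[f"bn_var_{i}"].copy()
        return model


def build_model(config: ModelConfig) -> MultiTaskModel:
    """Construct the detection network for the given topology and tasks."""
    return MultiTaskModel(config)
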