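"""Trainable 2D classifiers for montage images.

Three architectures, all emitting a single logit through one uniform
``predict_proba`` surface so the evaluation protocol and the
explanation engine are architecture-agnostic:

* ``lightweight`` — six repeats of conv→ReLU→maxpool(2), then a fully
  connected head; trained with RMSProp;
* ``resnet18_finetune`` — a ResNet-18 topology (7×7 stem, four stages of
  two residual basic blocks, global average pool) with the single-channel
  input replicated to three channels and a one-logit head; trained with
  SGD.  ImageNet initial weights require a local weights file; without one
  the ``pretrained`` flag raises and randomly initialised weights are used;
* ``early_fusion_resnet18`` — the pooled final-stage ResNet features
  concatenated with the three tabular values before the head.

Models run on the package's own numpy engine (:mod:`neuromontage.nn`), so
they need no GPU stack; widths are configurable for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["ModelSpec", "Classifier", "build_lightweight",
           "build_resnet18_adapter", "build_early_fusion", "build_model",
           "encode_tabular"]

ARCHITECTURES = ("lightweight", "resnet18_finetune", "early_fusion_resnet18")
DEFAULT_OPTIMIZER = {"lightweight": "rmsprop",
                     "resnet18_finetune": "sgd",
                     "early_fusion_resnet18": "sgd"}


@dataclass(frozen=True)
class ModelSpec:
    architecture: str = "lightweight"
    input_side: int = 256
    pretrained: bool = False
    optimizer: str | None = None       # None → architecture default
    learning_rate: float = 1e-4
    # lightweight channel widths; the historical filter counts are not
    # published, these defaults are frozen here and fully configurable
    widths: tuple[int, ...] = (16, 32, 64, 64, 128, 128)
    resnet_width: int = 64             # stem width; stages double it
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def resolved_optimizer(self) -> str:
        return self.optimizer or DEFAULT_OPTIMIZER[self.architecture]


class Classifier:
    """A trained or trainable binary classifier with a probability surface."""

    def __init__(self, net: nn.Layer, spec: ModelSpec,
                 uses_tabular: bool = False):
        self.net = net
        self.spec = spec
        self.uses_tabular = uses_tabular

    # -- inference ---------------------------------------------------------
    def predict_logits(self, images: np.ndarray,
                       tabular: np.ndarray | None = None) -> np.ndarray:
        x = self._as_batch(images)
        self.net.eval()
        if self.uses_tabular:
            if tabular is None:
                raise ValueError("this model requires a tabular matrix")
            tab = np.atleast_2d(np.asarray(tabular, dtype=np.float64))
            if tab.shape != (x.shape[0], 3):
                raise ValueError("tabular matrix must be (n, 3)")
            logits = self.net.forward((x, tab))
        else:
            logits = self.net.forward(x)
        return logits.reshape(-1)

    def predict_proba(self, images: np.ndarray,
                      tabular: np.ndarray | None = None) -> np.ndarray:
        return nn.sigmoid(self.predict_logits(images, tabular))

    @staticmethod
    def _as_batch(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        elif x.ndim != 4:
            raise ValueError("images must be 2D, 3D (n,h,w) or 4D (n,c,h,w)")
        return x

    # -- training ----------------------------------------------------------
    def make_optimizer(self, learning_rate: float | None = None):
        lr = learning_rate or self.spec.learning_rate
        params = self.net.parameters()
        if self.spec.resolved_optimizer == "rmsprop":
            return nn.RMSProp(params, lr)
        return nn.SGD(params, lr)

    def train_step(self, optimizer, images, labels, weights=None,
                   tabular=None) -> float:
        x = self._as_batch(images)
        self.net.train(True)
        optimizer.zero_grad()
        if self.uses_tabular:
            logits = self.net.forward((x, tabular)).reshape(-1)
        else:
            logits = self.net.forward(x).reshape(-1)
        loss, dlogit = nn.bce_with_logits(logits, labels, weights)
        self.net.backward(dlogit.reshape(-1, 1))
        optimizer.step()
        return loss

    # -- state -------------------------------------------------------------
    def parameter_checksum(self) -> int:
        return nn.parameter_checksum(self.net.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.net.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.net.parameters():
            p.value[...] = state[p.name]


def build_lightweight(spec: ModelSpec) -> Classifier:
    """Six conv→ReLU→maxpool(2) blocks, flatten, fully connected head."""
    if spec.input_side % 64 != 0:
        raise ValueError("input side must be divisible by 2**6")
    rng = np.random.default_rng(spec.seed)
    layers: list[nn.Layer] = []
    cin = 1
    for i, cout in enumerate(spec.widths):
        layers += [nn.Conv2d(cin, cout, 3, rng=rng, name=f"b{i}.conv"),
                   nn.ReLU(), nn.MaxPool2d(2)]
        cin = cout
    side = spec.input_side // 2 ** len(spec.widths)
    layers += [nn.Flatten(),
               nn.Linear(cin * side * side, 1, rng=rng, name="head")]
    return Classifier(nn.Sequential(*layers), spec)


class _ResNetBackbone(nn.Layer):
    """ResNet-18 topology producing pooled feature vectors.

    A single-channel input is replicated to three channels (the adapter
    convention for grayscale scans through an RGB backbone).
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        w = spec.resnet_width
        self.stem = nn.Sequential(
            nn.Conv2d(3, w, 7, stride=2, pad=3, rng=rng, bias=False,
                      name="stem.conv"),
            nn.BatchNorm2d(w, name="stem.bn"), nn.ReLU(),
            nn.MaxPool2d(3, stride=2, pad=1))
        blocks: list[nn.Layer] = []
        cin = w
        for stage, mult in enumerate((1, 2, 4, 8)):
            cout = w * mult
            stride = 1 if stage == 0 else 2
            blocks.append(nn.BasicBlock(cin, cout, stride=stride, rng=rng,
                                        name=f"s{stage}.b0"))
            blocks.append(nn.BasicBlock(cout, cout, rng=rng,
                                        name=f"s{stage}.b1"))
            cin = cout
        self.blocks = nn.Sequential(*blocks)
        self.pool = nn.GlobalAvgPool()
        self.feature_dim = cin

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == 1:
            x = np.repeat(x, 3, axis=1)
            self._replicated = True
        else:
            self._replicated = False
        return self.pool(self.blocks(self.stem(x)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.stem.backward(self.blocks.backward(self.pool.backward(grad)))
        if self._replicated:
            g = g.sum(axis=1, keepdims=True)
        return g

    def parameters(self) -> list[nn.Param]:
        return (self.stem.parameters() + self.blocks.parameters())

    def train(self, mode: bool = True) -> "_ResNetBackbone":
        self.training = mode
        for sub in (self.stem, self.blocks, self.pool):
            sub.train(mode)
        return self


class _ResNetClassifierNet(nn.Layer):
    def __init__(self, backbone: _ResNetBackbone, head: nn.Linear):
        self.backbone, self.head = backbone, head

    def forward(self, x):
        return self.head(self.backbone(x))

    def backward(self, grad):
        return self.backbone.backward(self.head.backward(grad))

    def parameters(self):
        return self.backbone.parameters() + self.head.parameters()

    def train(self, mode: bool = True):
        self.training = mode
        self.backbone.train(mode)
        self.head.train(mode)
        return self


class _EarlyFusionNet(nn.Layer):
    """Backbone features ⧺ 3 tabular values → fully connected → logit."""

    def __init__(self, backbone: _ResNetBackbone, head: nn.Linear):
        self.backbone, self.head = backbone, head

    def forward(self, xt):
        x, tab = xt
        feats = self.backbone(x)
        fused = np.concatenate([feats, np.asarray(tab, dtype=np.float64)],
                               axis=1)
        self._ntab = 3
        return self.head(fused)

    def backward(self, grad):
        g = self.head.backward(grad)
        return self.backbone.backward(g[:, :-self._ntab])

    def parameters(self):
        return self.backbone.parameters() + self.head.parameters()

    def train(self, mode: bool = True):
        self.training = mode
        self.backbone.train(mode)
        self.head.train(mode)
        return self


def _check_pretrained(spec: ModelSpec) -> None:
    if spec.pretrained:
        raise FileNotFoundError(
            "no local ImageNet weights file is available for the ResNet-18 "
            "backbone; build with pretrained=False or supply weights")


def build_resnet18_adapter(spec: ModelSpec) -> Classifier:
    """ResNet-18 with replicated grayscale input and a single-logit head."""
    _check_pretrained(spec)
    rng = np.random.default_rng(spec.seed)
    backbone = _ResNetBackbone(spec, rng)
    head = nn.Linear(backbone.feature_dim, 1, rng=rng, name="head")
    return Classifier(_ResNetClassifierNet(backbone, head), spec)


def build_early_fusion(spec: ModelSpec) -> Classifier:
    """ResNet-18 features concatenated with the three tabular values."""
    _check_pretrained(spec)
    rng = np.random.default_rng(spec.seed)
    backbone = _ResNetBackbone(spec, rng)
    head = nn.Linear(backbone.feature_dim + 3, 1, rng=rng, name="head")
    return Classifier(_EarlyFusionNet(backbone, head), spec,
                      uses_tabular=True)


def build_model(spec: ModelSpec) -> Classifier:
    builders = {"lightweight": build_lightweight,
                "resnet18_finetune": build_resnet18_adapter,
                "early_fusion_resnet18": build_early_fusion}
    return builders[spec.architecture](spec)


def encode_tabular(table, train_index=None) -> np.ndarray:
    """(n, 3) numeric matrix for early fusion.

    Severity enters as an integer-like code with "unknown" as its own
    level; the continuous columns are standardised with training-split
    statistics only (``train_index``, default all rows).
    """
    from .synthetic import SEVERITY_CODE

    sev = table["initial_severity"].map(SEVERITY_CODE).to_numpy(dtype=float)
    size = table["left_lesion_size"].to_numpy(dtype=float)
    rec = table["recovery_time_months"].to_numpy(dtype=float)
    out = np.stack([sev, size, rec], axis=1)
    idx = np.arange(len(table)) if train_index is None \
        else np.asarray(train_index)
    mu = out[idx].mean(axis=0)
    sd = out[idx].std(axis=0)
    sd[sd == 0] = 1.0
    return (out - mu) / sd
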