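"""Multi-output CNN for TI-RADS feature and malignancy classification.

A shared convolutional backbone (skip-connection or dense-connection style)
feeds, via global average pooling, one linear head per output surface:
malignancy, composition, echogenicity, margin, and four independent
echogenic-foci detectors.  Two head designs are supported:

* ``v1`` — composition, echogenicity and margin are plain softmax
  classifiers (4 classes each); malignancy and each focus are logistic.
* ``v2`` — the refactored design: composition becomes three independent
  logistic outputs (cystic, solid, spongiform) with "mixed" decided
  programmatically when both cystic and solid exceed a threshold;
  echogenicity becomes a single linear regression output with integer
  targets 0..3 coding hyperechoic, hypoechoic, very hypoechoic, anechoic;
  the margin head merges ill-defined with smooth (3 classes), which is
  score-neutral because both margin classes carry zero TI-RADS points.

The total training loss is the unweighted sum of eight per-head terms:
L_all = L_m + L_p + L_a + L_b + L_c + L_d + L_e + L_f (malignancy,
composition, comet-tail, micro-, macro-, peripheral-calcification,
echogenicity, margin).

Everything here is plain NumPy: convolutions are im2col matrix products
and every layer implements an explicit backward pass, which both drives
Adam training and exposes the activation gradients that Grad-CAM needs.
Full-scale ``resnet50``/``densenet201`` backbones are constructible from
the same block families for completeness; the ``tiny_*`` backbones are the
practical CPU-scale default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "HeadConfig",
    "HeadOutputs",
    "LabelSet",
    "LossBreakdown",
    "MultiHeadModel",
    "build_model",
    "forward",
    "total_loss",
    "decide_composition",
    "decide_echogenicity",
    "decide_margin",
    "decide_malignant",
    "decide_foci",
    "train",
    "evaluate",
    "V1_COMPOSITION_CLASSES",
    "V2_COMPOSITION_COMPONENTS",
    "ECHOGENICITY_CODE_ORDER",
    "V1_MARGIN_CLASSES",
    "V2_MARGIN_CLASSES",
    "FOCI_ORDER",
]

# Class orders are fixed so logits/probabilities index consistently.
V1_COMPOSITION_CLASSES = ("cystic", "solid", "mixed", "spongiform")
V2_COMPOSITION_COMPONENTS = ("cystic", "solid", "spongiform")
#: integer code order for echogenicity: code 0 = hyperechoic ... 3 = anechoic
ECHOGENICITY_CODE_ORDER = ("hyperechoic", "hypoechoic", "very_hypoechoic", "anechoic")
V1_MARGIN_CLASSES = (
    "smooth",
    "ill_defined",
    "lobulated_irregular",
    "extrathyroidal_extension",
)
V2_MARGIN_CLASSES = (
    "smooth_or_ill_defined",
    "lobulated_irregular",
    "extrathyroidal_extension",
)
#: focus order matches the loss terms L_a..L_d
FOCI_ORDER = (
    "comet_tail",
    "punctate_micro",
    "macrocalcification",
    "peripheral_calcification",
)

_EPS = 1e-7


# --------------------------------------------------------------------------
# configuration and label/output containers
# --------------------------------------------------------------------------

@dataclass
class HeadConfig:
    """Network configuration: head design version and backbone choice."""

    version: str = "v1"
    backbone: str = "tiny_resnet"
    pretrained: bool = False
    mixed_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.version not in ("v1", "v2"):
            raise ValueError(f"unknown head version {self.version!r}")
        if self.backbone not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; options: {sorted(_BACKBONES)}"
            )
        if not 0.0 < self.mixed_threshold < 1.0:
            raise ValueError("mixed_threshold must lie in (0, 1)")
        if self.pretrained:
            raise ValueError(
                "no pretrained weights are bundled; train from scratch "
                "(pretrained=False)"
            )


@dataclass
class LabelSet:
    """Ground truth for one nodule, one value per head.

    ``margin`` uses the 4-class axis; the v2 3-class head folds
    ``ill_defined`` into ``smooth_or_ill_defined`` automatically.
    """

    malignant: bool
    composition: str
    echogenicity: str
    margin: str
    foci: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.composition not in V1_COMPOSITION_CLASSES:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.echogenicity not in ECHOGENICITY_CODE_ORDER:
            raise ValueError(f"unknown echogenicity {self.echogenicity!r}")
        if self.margin not in V1_MARGIN_CLASSES:
            raise ValueError(f"unknown margin {self.margin!r}")
        self.foci = frozenset(self.foci)
        for f in self.foci:
            if f not in FOCI_ORDER:
                raise ValueError(f"unknown focus {f!r}")

    @property
    def echogenicity_code(self) -> int:
        """Integer code 0..3 (hyper, hypo, very hypo, anechoic)."""
        return ECHOGENICITY_CODE_ORDER.index(self.echogenicity)

    @property
    def margin_v2(self) -> str:
        if self.margin in ("smooth", "ill_defined"):
            return "smooth_or_ill_defined"
        return self.margin

    def composition_components(self) -> np.ndarray:
        """v2 targets (cystic, solid, spongiform); mixed sets both cystic+solid."""
        vec = np.zeros(3)
        if self.composition == "mixed":
            vec[0] = vec[1] = 1.0
        else:
            vec[V2_COMPOSITION_COMPONENTS.index(self.composition)] = 1.0
        return vec


@dataclass
class HeadOutputs:
    """Per-head probabilities for a batch (N rows).

    ``composition`` is an (N,4) simplex in v1 or (N,3) independent sigmoid
    probabilities in v2; ``echogenicity`` is an (N,4) simplex in v1 or an
    (N,) real regression output in v2; ``margin`` is (N,4) in v1, (N,3) in
    v2; ``p_malignant`` is (N,); ``foci`` is (N,4) independent
    probabilities ordered as :data:`FOCI_ORDER`.
    """

    version: str
    p_malignant: np.ndarray
    composition: np.ndarray
    echogenicity: np.ndarray
    margin: np.ndarray
    foci: np.ndarray


@dataclass(frozen=True)
class LossBreakdown:
    """The eight loss terms and their plain (unweighted) sum."""

    L_m: float  # malignant/benign
    L_p: float  # composition
    L_a: float  # comet-tail focus
    L_b: float  # micro-calcification focus
    L_c: float  # macro-calcification focus
    L_d: float  # peripheral-calcification focus
    L_e: float  # echogenicity
    L_f: float  # margin
    L_all: float

    @staticmethod
    def from_terms(L_m, L_p, L_a, L_b, L_c, L_d, L_e, L_f) -> "LossBreakdown":
        total = L_m + L_p + L_a + L_b + L_c + L_d + L_e + L_f
        return LossBreakdown(L_m, L_p, L_a, L_b, L_c, L_d, L_e, L_f, total)


# --------------------------------------------------------------------------
# layers (im2col convolution and friends, explicit backward passes)
# --------------------------------------------------------------------------

class _Conv2d:
    def __init__(self, rng, c_in, c_out, k, stride=1, pad=None):
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]          # n,c,ho,wo,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return out

    def backward(self, g):
        cols, x_shape, xp_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        c_out = self.W.shape[0]
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dW += (g2.T @ cols).reshape(self.W.shape)
        self.db += g2.sum(axis=0)
        dcols = (g2 @ self.W.reshape(c_out, -1)).reshape(n, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)           # n,c,ho,wo,k,k
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)

    def params(self):
        return []


class _AvgPool2:
    """2x2 average pooling with stride 2 (even input sides assumed)."""

    def forward(self, x):
        self._shape = x.shape
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, g):
        n, c, h, w = self._shape
        up = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        return up

    def params(self):
        return []


class _Linear:
    def __init__(self, rng, n_in, n_out):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        self.dW += g.T @ self._x
        self.db += g.sum(axis=0)
        return g @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ResidualBlock:
    """conv(s)-relu-conv(1) with a 1x1 strided shortcut, post-add ReLU."""

    def __init__(self, rng, c_in, c_out, stride):
        self.conv1 = _Conv2d(rng, c_in, c_out, 3, stride)
        self.relu1 = _ReLU()
        self.conv2 = _Conv2d(rng, c_out, c_out, 3, 1)
        self.short = _Conv2d(rng, c_in, c_out, 1, stride, pad=0)
        self.relu2 = _ReLU()

    def forward(self, x):
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(main + self.short.forward(x))

    def backward(self, g):
        g = self.relu2.backward(g)
        g_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        g_short = self.short.backward(g)
        return g_main + g_short

    def params(self):
        return (self.conv1.params() + self.conv2.params() + self.short.params())


class _DenseBlock:
    """Dense connectivity: each 3x3 conv sees the concat of all previous maps."""

    def __init__(self, rng, c_in, growth, n_layers):
        self.convs = []
        self.relus = []
        c = c_in
        for _ in range(n_layers):
            self.convs.append(_Conv2d(rng, c, growth, 3, 1))
            self.relus.append(_ReLU())
            c += growth
        self.c_out = c

    def forward(self, x):
        self._in_channels = [x.shape[1]]
        feats = x
        for conv, relu in zip(self.convs, self.relus):
            new = relu.forward(conv.forward(feats))
            feats = np.concatenate([feats, new], axis=1)
            self._in_channels.append(feats.shape[1])
        return feats

    def backward(self, g):
        for conv, relu, c_prev in zip(
            reversed(self.convs), reversed(self.relus), reversed(self._in_channels[:-1])
        ):
            g_prev, g_new = g[:, :c_prev], g[:, c_prev:]
            g = g_prev + conv.backward(relu.backward(g_new))
        return g

    def params(self):
        return [p for conv in self.convs for p in conv.params()]


class _Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


# --------------------------------------------------------------------------
# backbones
# --------------------------------------------------------------------------

def _tiny_resnet(rng):
    layers = [
        _Conv2d(rng, 3, 16, 7, 4, pad=3),
        _ReLU(),
        _ResidualBlock(rng, 16, 32, 2),
        _ResidualBlock(rng, 32, 48, 2),
        _ResidualBlock(rng, 48, 64, 2),
        _ResidualBlock(rng, 64, 64, 2),
    ]
    return _Sequential(layers), 64


def _tiny_densenet(rng):
    db1 = _DenseBlock(rng, 16, 8, 3)
    db2 = _DenseBlock(rng, 24, 8, 3)
    layers = [
        _Conv2d(rng, 3, 16, 7, 4, pad=3),
        _ReLU(),
        db1,
        _Conv2d(rng, db1.c_out, 24, 1, 1, pad=0),
        _ReLU(),
        _AvgPool2(),
        db2,
        _Conv2d(rng, db2.c_out, 64, 1, 1, pad=0),
        _ReLU(),
        _AvgPool2(),
    ]
    return _Sequential(layers), 64


def _micro(rng):
    """Minimal 2-convolution backbone used for gradient checking."""
    layers = [
        _Conv2d(rng, 3, 8, 3, 2),
        _ReLU(),
        _Conv2d(rng, 8, 8, 3, 1),
        _ReLU(),
    ]
    return _Sequential(layers), 8


def _resnet50_like(rng):
    # Full-depth skip-connection option (no pretrained weights available);
    # far heavier than the tiny variants and impractical without a GPU.
    layers = [_Conv2d(rng, 3, 64, 7, 4, pad=3), _ReLU()]
    c = 64
    for c_out, n in ((64, 3), (128, 4), (256, 6), (512, 3)):
        for i in range(n):
            layers.append(_ResidualBlock(rng, c, c_out, 2 if i == 0 else 1))
            c = c_out
    return _Sequential(layers), c


def _densenet201_like(rng):
    layers = [_Conv2d(rng, 3, 64, 7, 4, pad=3), _ReLU()]
    c = 64
    for n in (6, 12, 24, 16):
        db = _DenseBlock(rng, c, 32, n)
        layers.append(db)
        c = db.c_out // 2
        layers += [_Conv2d(rng, db.c_out, c, 1, 1, pad=0), _ReLU(), _AvgPool2()]
    return _Sequential(layers), c


_BACKBONES = {
    "tiny_resnet": _tiny_resnet,
    "tiny_densenet": _tiny_densenet,
    "micro": _micro,
    "resnet50": _resnet50_like,
    "densenet201": _densenet201_like,
}

_HEAD_SIZES = {
    "v1": {"malignancy": 1, "composition": 4, "echogenicity": 4, "margin": 4, "foci": 4},
    "v2": {"malignancy": 1, "composition": 3, "echogenicity": 1, "margin": 3, "foci": 4},
}


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadModel:
    """Backbone + global average pooling + one linear head per output."""

    def __init__(self, cfg: HeadConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.backbone, self.n_features = _BACKBONES[cfg.backbone](rng)
        self.heads: Dict[str, _Linear] = {
            name: _Linear(rng, self.n_features, size)
            for name, size in _HEAD_SIZES[cfg.version].items()
        }
        self._feature_shape: Optional[Tuple[int, ...]] = None

    # -- forward ----------------------------------------------------------
    def forward_features(self, stacks: np.ndarray) -> np.ndarray:
        """Backbone feature map (N, C, h, w) — the Grad-CAM target layer."""
        stacks = np.asarray(stacks, dtype=np.float64)
        if stacks.ndim == 3:
            stacks = stacks[None]
        if stacks.ndim != 4 or stacks.shape[1] != 3:
            raise ValueError(
                f"expected (N, 3, H, W) input, got shape {stacks.shape}"
            )
        feats = self.backbone.forward(stacks)
        self._feature_shape = feats.shape
        return feats

    def logits_from_features(self, feats: np.ndarray) -> Dict[str, np.ndarray]:
        pooled = feats.mean(axis=(2, 3))
        return {name: head.forward(pooled) for name, head in self.heads.items()}

    def forward_logits(self, stacks: np.ndarray) -> Dict[str, np.ndarray]:
        return self.logits_from_features(self.forward_features(stacks))

    def feature_gradient(
        self, feats: np.ndarray, head: str, class_index: int
    ) -> np.ndarray:
        """d(head logit for class)/d(feature map), via head+pool backward.

        Must follow a :meth:`logits_from_features` call on the same batch
        (the linear heads cache their pooled input).
        """
        if head not in self.heads:
            raise ValueError(f"unknown head {head!r}")
        lin = self.heads[head]
        n_out = lin.W.shape[0]
        if not 0 <= class_index < n_out:
            raise ValueError(f"class_index {class_index} out of range for {head!r}")
        n, c, h, w = feats.shape
        g_logit = np.zeros((n, n_out))
        g_logit[:, class_index] = 1.0
        g_pooled = g_logit @ lin.W                       # (n, C)
        return np.broadcast_to(g_pooled[:, :, None, None], (n, c, h, w)) / (h * w)

    # -- backward / optimisation ------------------------------------------
    def zero_grad(self) -> None:
        for p, g in self.parameters():
            g[...] = 0.0

    def parameters(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        params = list(self.backbone.params())
        for head in self.heads.values():
            params += head.params()
        return params

    def backward_from_logit_grads(
        self, feats: np.ndarray, logit_grads: Dict[str, np.ndarray]
    ) -> None:
        """Accumulate parameter gradients given d(loss)/d(logits) per head."""
        n, c, h, w = feats.shape
        g_pooled = np.zeros((n, c))
        for name, g in logit_grads.items():
            g_pooled += self.heads[name].backward(g)
        g_feats = np.broadcast_to(g_pooled[:, :, None, None], feats.shape) / (h * w)
        self.backbone.backward(np.ascontiguousarray(g_feats))

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"param_{i}": p for i, (p, _) in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.parameters()):
            p[...] = state[f"param_{i}"]

    def save(self, path: str) -> None:
        import json

        meta = {
            "version": self.cfg.version,
            "backbone": self.cfg.backbone,
            "mixed_threshold": self.cfg.mixed_threshold,
            "seed": self.seed,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "MultiHeadModel":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg = HeadConfig(
            version=meta["version"],
            backbone=meta["backbone"],
            mixed_threshold=meta["mixed_threshold"],
        )
        model = cls(cfg, seed=meta["seed"])
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


def build_model(cfg: HeadConfig, seed: int = 0) -> MultiHeadModel:
    """Seeded model construction (He-initialised weights)."""
    return MultiHeadModel(cfg, seed)


# --------------------------------------------------------------------------
# forward to probabilities
# --------------------------------------------------------------------------

def outputs_from_logits(logits: Dict[str, np.ndarray], cfg: HeadConfig) -> HeadOutputs:
    if cfg.version == "v1":
        comp = _softmax(logits["composition"])
        echo = _softmax(logits["echogenicity"])
    else:
        comp = _sigmoid(logits["composition"])
        echo = logits["echogenicity"][:, 0]
    margin = _softmax(logits["margin"])
    return HeadOutputs(
        version=cfg.version,
        p_malignant=_sigmoid(logits["malignancy"][:, 0]),
        composition=comp,
        echogenicity=echo,
        margin=margin,
        foci=_sigmoid(logits["foci"]),
    )


def forward(stack, model: MultiHeadModel) -> HeadOutputs:
    """Run the network on an input stack (or batch) and return probabilities."""
    from .preprocess import InputStack

    if isinstance(stack, InputStack):
        stack = stack.planes
    return outputs_from_logits(model.forward_logits(stack), model.cfg)


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def _ce(p: np.ndarray, idx: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0)
    return float(np.mean(-np.log(p[np.arange(len(idx)), idx])))


def _label_arrays(labels: Sequence[LabelSet], version: str) -> Dict[str, np.ndarray]:
    malignant = np.array([float(l.malignant) for l in labels])
    foci = np.array(
        [[float(f in l.foci) for f in FOCI_ORDER] for l in labels]
    )
    out = {"malignant": malignant, "foci": foci}
    if version == "v1":
        out["composition"] = np.array(
            [V1_COMPOSITION_CLASSES.index(l.composition) for l in labels]
        )
        out["echogenicity"] = np.array([l.echogenicity_code for l in labels])
        out["margin"] = np.array([V1_MARGIN_CLASSES.index(l.margin) for l in labels])
    else:
        out["composition"] = np.array([l.composition_components() for l in labels])
        out["echogenicity"] = np.array([float(l.echogenicity_code) for l in labels])
        out["margin"] = np.array([V2_MARGIN_CLASSES.index(l.margin_v2) for l in labels])
    return out


def total_loss(
    out: HeadOutputs, labels: Sequence[LabelSet], cfg: HeadConfig
) -> LossBreakdown:
    """Eight-term combined loss, averaged over the batch per term.

    v1 uses cross-entropy throughout (binary for malignancy and each
    focus).  v2 replaces the composition term with the sum of three
    per-component binary cross-entropies, and the echogenicity term with
    the mean squared error to the integer class code.
    """
    if out.version != cfg.version:
        raise ValueError(
            f"outputs are {out.version!r} but config is {cfg.version!r}"
        )
    n = len(out.p_malignant)
    if len(labels) != n:
        raise ValueError(f"{n} outputs vs {len(labels)} labels")
    y = _label_arrays(labels, cfg.version)

    L_m = _bce(out.p_malignant, y["malignant"])
    L_a = _bce(out.foci[:, 0], y["foci"][:, 0])
    L_b = _bce(out.foci[:, 1], y["foci"][:, 1])
    L_c = _bce(out.foci[:, 2], y["foci"][:, 2])
    L_d = _bce(out.foci[:, 3], y["foci"][:, 3])
    L_f = _ce(out.margin, y["margin"])
    if cfg.version == "v1":
        L_p = _ce(out.composition, y["composition"])
        L_e = _ce(out.echogenicity, y["echogenicity"])
    else:
        L_p = sum(
            _bce(out.composition[:, j], y["composition"][:, j]) for j in range(3)
        )
        L_e = float(np.mean((out.echogenicity - y["echogenicity"]) ** 2))
    return LossBreakdown.from_terms(L_m, L_p, L_a, L_b, L_c, L_d, L_e, L_f)


def _logit_gradients(
    logits: Dict[str, np.ndarray],
    labels: Sequence[LabelSet],
    cfg: HeadConfig,
) -> Dict[str, np.ndarray]:
    """d(L_all)/d(logits) for every head (batch-mean losses)."""
    n = len(labels)
    y = _label_arrays(labels, cfg.version)
    grads: Dict[str, np.ndarray] = {}
    grads["malignancy"] = (
        _sigmoid(logits["malignancy"]) - y["malignant"][:, None]
    ) / n
    grads["foci"] = (_sigmoid(logits["foci"]) - y["foci"]) / n
    p_margin = _softmax(logits["margin"])
    onehot_m = np.eye(p_margin.shape[1])[y["margin"]]
    grads["margin"] = (p_margin - onehot_m) / n
    if cfg.version == "v1":
        p_comp = _softmax(logits["composition"])
        grads["composition"] = (p_comp - np.eye(4)[y["composition"]]) / n
        p_echo = _softmax(logits["echogenicity"])
        grads["echogenicity"] = (p_echo - np.eye(4)[y["echogenicity"]]) / n
    else:
        grads["composition"] = (
            _sigmoid(logits["composition"]) - y["composition"]
        ) / n
        yhat = logits["echogenicity"][:, 0]
        grads["echogenicity"] = (2.0 * (yhat - y["echogenicity"]) / n)[:, None]
    return grads


# --------------------------------------------------------------------------
# decision rules
# --------------------------------------------------------------------------

def decide_malignant(out: HeadOutputs) -> np.ndarray:
    return out.p_malignant > 0.5


def decide_composition(out: HeadOutputs, cfg: HeadConfig) -> List[str]:
    """Composition class per sample.

    v1: arg-max over the 4-class simplex.  v2: "mixed" iff both the cystic
    and solid sigmoids strictly exceed the threshold (default 0.5);
    otherwise the arg-max of the three component probabilities.
    """
    if cfg.version == "v1":
        return [V1_COMPOSITION_CLASSES[i] for i in out.composition.argmax(axis=1)]
    thr = cfg.mixed_threshold
    decisions = []
    for p_c, p_s, p_g in out.composition:
        if p_c > thr and p_s > thr:
            decisions.append("mixed")
        else:
            decisions.append(
                V2_COMPOSITION_COMPONENTS[int(np.argmax([p_c, p_s, p_g]))]
            )
    return decisions


def decide_echogenicity(y) -> str:
    """Echogenicity class from the v2 regression output.

    Rounds to the nearest integer code (ties, x.5, round half away from
    zero), clamps to [0, 3], and maps through the code order hyperechoic,
    hypoechoic, very hypoechoic, anechoic.
    """
    y = float(y)
    if not np.isfinite(y):
        raise ValueError(f"echogenicity output must be finite, got {y}")
    code = math.floor(y + 0.5) if y >= 0 else math.ceil(y - 0.5)
    code = min(3, max(0, code))
    return ECHOGENICITY_CODE_ORDER[code]


def _decide_echogenicity_batch(out: HeadOutputs) -> List[str]:
    if out.version == "v1":
        return [ECHOGENICITY_CODE_ORDER[i] for i in out.echogenicity.argmax(axis=1)]
    return [decide_echogenicity(v) for v in out.echogenicity]


def decide_margin(out: HeadOutputs) -> List[str]:
    classes = V1_MARGIN_CLASSES if out.version == "v1" else V2_MARGIN_CLASSES
    return [classes[i] for i in out.margin.argmax(axis=1)]


def decide_foci(out: HeadOutputs) -> List[FrozenSet[str]]:
    return [
        frozenset(f for f, p in zip(FOCI_ORDER, row) if p > 0.5) for row in out.foci
    ]


def margin_to_rules(margin_class: str) -> str:
    """Map a predicted margin class onto the scoring axis.

    The merged v2 class scores like "smooth" (both members carry 0 points).
    """
    return "smooth" if margin_class == "smooth_or_ill_defined" else margin_class


# --------------------------------------------------------------------------
# training and evaluation
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr=3e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        corr1 = 1.0 - self.b1 ** self.t
        corr2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def _as_arrays(dataset) -> Tuple[np.ndarray, List[LabelSet]]:
    if hasattr(dataset, "stacks") and hasattr(dataset, "labels"):
        return np.asarray(dataset.stacks, dtype=np.float64), list(dataset.labels)
    stacks, labels = dataset
    return np.asarray(stacks, dtype=np.float64), list(labels)


def train(
    dataset,
    cfg: HeadConfig,
    epochs: int = 5,
    seed: int = 0,
    lr: float = 3e-3,
    batch_size: int = 16,
    model: Optional[MultiHeadModel] = None,
) -> Tuple[MultiHeadModel, List[LossBreakdown]]:
    """Adam training of the multi-head model on (stacks, labels).

    ``dataset`` is either a ``(stacks, labels)`` pair — stacks of shape
    (N, 3, H, W), labels a sequence of :class:`LabelSet` — or any object
    with ``.stacks``/``.labels``.  Returns the trained model and one
    batch-averaged :class:`LossBreakdown` per epoch.  Fully reproducible
    given ``seed`` on a single device.
    """
    stacks, labels = _as_arrays(dataset)
    n = len(labels)
    if n == 0:
        raise ValueError("empty dataset")
    if model is None:
        model = build_model(cfg, seed)
    opt = _Adam(model.parameters(), lr=lr)
    shuffle_rng = np.random.default_rng(seed + 1)
    history: List[LossBreakdown] = []
    for _ in range(epochs):
        order = shuffle_rng.permutation(n)
        terms = np.zeros(8)
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch_labels = [labels[i] for i in idx]
            feats = model.forward_features(stacks[idx])
            logits = model.logits_from_features(feats)
            lb = total_loss(outputs_from_logits(logits, cfg), batch_labels, cfg)
            terms += [lb.L_m, lb.L_p, lb.L_a, lb.L_b, lb.L_c, lb.L_d, lb.L_e, lb.L_f]
            n_batches += 1
            model.zero_grad()
            model.backward_from_logit_grads(
                feats, _logit_gradients(logits, batch_labels, cfg)
            )
            opt.step()
        history.append(LossBreakdown.from_terms(*(terms / n_batches)))
    return model, history


#: evaluation rows, mirroring the per-head accuracy-table layout
EVAL_ROWS = (
    "malignancy",
    "composition",
    "echogenicity",
    "margin",
    "comet_tail",
    "macrocalcification",
    "peripheral_calcification",
    "punctate_micro",
)


def evaluate(
    model: MultiHeadModel, dataset, cfg: Optional[HeadConfig] = None,
    batch_size: int = 32,
) -> Dict[str, float]:
    """Per-head accuracy (%) using the version's decision rules.

    Margin accuracy is judged on the head's own class set (v2 compares
    against the merged smooth/ill-defined label).
    """
    cfg = cfg or model.cfg
    stacks, labels = _as_arrays(dataset)
    n = len(labels)
    correct = {row: 0 for row in EVAL_ROWS}
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        out = forward(stacks[sl], model)
        batch = labels[sl]
        for pred, lab in zip(decide_malignant(out), batch):
            correct["malignancy"] += int(bool(pred) == bool(lab.malignant))
        for pred, lab in zip(decide_composition(out, cfg), batch):
            correct["composition"] += int(pred == lab.composition)
        for pred, lab in zip(_decide_echogenicity_batch(out), batch):
            correct["echogenicity"] += int(pred == lab.echogenicity)
        for pred, lab in zip(decide_margin(out), batch):
            target = lab.margin if cfg.version == "v1" else lab.margin_v2
            correct["margin"] += int(pred == target)
        for pred, lab in zip(decide_foci(out), batch):
            for f in FOCI_ORDER:
                correct[f] += int((f in pred) == (f in lab.foci))
    return {row: 100.0 * correct[row] / n for row in EVAL_ROWS}
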