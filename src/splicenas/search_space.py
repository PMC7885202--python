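"""Candidate operation set and the softmax-mixed edge.

The search space is a fixed set of eight feature-map primitives.  Every
convolutional primitive follows the ReLU -> convolution -> batch-norm order;
separable convolutions factor into a depthwise stage followed by a pointwise
stage.  A :class:`MixedEdge` holds one architecture-parameter vector ``alpha``
per edge and applies the softmax-weighted sum of all primitive outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from . import nnops

#: Canonical primitive names, in the order used for alpha vectors and
#: genotype files.
PRIMITIVES = (
    "sep_conv_3x3",
    "sep_conv_5x5",
    "sep_conv_7x7",
    "dil_conv_3x3",
    "conv_7x1_1x7",
    "max_pool_3x3",
    "avg_pool_3x3",
    "zero",
)

ZERO_OP = "zero"


@dataclass(frozen=True)
class PrimitiveSpec:
    """Description of one candidate operation on an edge."""

    name: str
    stride: int = 1
    channels_in: int = 1
    channels_out: int = 1

    def __post_init__(self):
        if self.name not in PRIMITIVES:
            raise ValueError(f"unknown primitive {self.name!r}; valid: {PRIMITIVES}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.channels_in <= 0 or self.channels_out <= 0:
            raise ValueError("channel counts must be positive")


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Primitive:
    """A parameterized feature-map transform built from a :class:`PrimitiveSpec`.

    ``init_params(rng)`` draws the trainable parameters as a (possibly empty)
    dict of arrays; ``__call__(params, x)`` applies the transform.  Pooling
    primitives are parameter-free; pass ``bn_after_pool=True`` to append a
    non-affine batch normalization so pooled outputs are scale-comparable to
    convolutional ones inside a mixed edge.
    """

    def __init__(self, spec: PrimitiveSpec, bn_after_pool: bool = False):
        self.spec = spec
        self.bn_after_pool = bn_after_pool
        name = spec.name
        if name.startswith("sep_conv"):
            self.kernel = int(name[-3])
            self.dilation = 1
        elif name == "dil_conv_3x3":
            self.kernel = 3
            self.dilation = 2
        else:
            self.kernel = 3
            self.dilation = 1

    # -- parameters ---------------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> dict:
        s = self.spec
        name = s.name
        if name.startswith("sep_conv") or name == "dil_conv_3x3":
            k = self.kernel
            return {
                "dw": _he(rng, (s.channels_in, k, k), k * k),
                "pw": _he(rng, (s.channels_out, s.channels_in, 1, 1), s.channels_in),
                "gamma": np.ones(s.channels_out, dtype=np.float32),
                "beta": np.zeros(s.channels_out, dtype=np.float32),
            }
        if name == "conv_7x1_1x7":
            return {
                "w1": _he(rng, (s.channels_out, s.channels_in, 7, 1), 7 * s.channels_in),
                "w2": _he(rng, (s.channels_out, s.channels_out, 1, 7), 7 * s.channels_out),
                "gamma": np.ones(s.channels_out, dtype=np.float32),
                "beta": np.zeros(s.channels_out, dtype=np.float32),
            }
        return {}  # pooling and zero are parameter-free

    # -- shape contract -----------------------------------------------------
    def output_shape(self, h: int, w: int):
        ho, wo = nnops.conv_output_shape(h, w, self.spec.stride)
        if ho <= 0 or wo <= 0:
            raise ValueError(f"{self.spec.name}: output spatial dimension would be 0")
        return ho, wo

    # -- forward ------------------------------------------------------------
    def __call__(self, params: dict, x):
        s = self.spec
        name = s.name
        if x.shape[2] <= 0 or x.shape[3] <= 0:
            raise ValueError("input spatial dimension is 0")
        if name == "zero":
            ho, wo = self.output_shape(x.shape[2], x.shape[3])
            dtype = getattr(x, "dtype", np.float64)
            return anp.zeros((x.shape[0], s.channels_out, ho, wo), dtype=dtype)
        if name in ("max_pool_3x3", "avg_pool_3x3"):
            pool = nnops.max_pool2d if name == "max_pool_3x3" else nnops.avg_pool2d
            out = pool(x, kernel=3, stride=s.stride)
            if self.bn_after_pool:
                out = nnops.batch_norm(out)
            return out
        h = nnops.relu(x)
        if name == "conv_7x1_1x7":
            h = nnops.conv2d(h, params["w1"], stride=(s.stride, 1))
            h = nnops.conv2d(h, params["w2"], stride=(1, s.stride))
        else:  # separable / dilated separable
            h = nnops.depthwise_conv2d(h, params["dw"], stride=s.stride, dilation=self.dilation)
            h = nnops.conv2d(h, params["pw"], stride=1)
        return nnops.batch_norm(h, params["gamma"], params["beta"])


def make_primitive(spec: PrimitiveSpec, bn_after_pool: bool = False) -> Primitive:
    """Build the feature-map transform for ``spec`` (validates the name)."""
    return Primitive(spec, bn_after_pool=bn_after_pool)


@dataclass
class MixedEdge:
    """One edge of the continuous search space.

    ``alpha`` has one entry per primitive; the edge output is the
    softmax(alpha)-weighted sum of all primitive outputs.  All primitives
    must share stride and output channels so their outputs are summable —
    this is checked at construction time.
    """

    alpha: np.ndarray
    primitives: list = field(default_factory=list)
    params: list = field(default_factory=list)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1 or len(self.alpha) != len(self.primitives):
            raise ValueError(
                f"alpha length {self.alpha.shape} does not match "
                f"{len(self.primitives)} primitives"
            )
        strides = {p.spec.stride for p in self.primitives}
        couts = {p.spec.channels_out for p in self.primitives}
        if len(strides) > 1 or len(couts) > 1:
            raise ValueError("primitives on one edge must share stride and output channels")

    def init_params(self, rng: np.random.Generator) -> None:
        self.params = [p.init_params(rng) for p in self.primitives]


def mixed_op_weights(edge: MixedEdge | np.ndarray) -> np.ndarray:
    """Softmax mixture weights of an edge's alpha vector."""
    alpha = edge.alpha if isinstance(edge, MixedEdge) else np.asarray(edge, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("alpha contains non-finite entries")
    return nnops.softmax(alpha)


def apply_mixed_op(edge: MixedEdge, x, params: list | None = None):
    """Apply the softmax-weighted sum of all primitive outputs to ``x``."""
    if params is None:
        params = edge.params
    if len(params) != len(edge.primitives):
        raise ValueError("need one params dict per primitive")
    weights = mixed_op_weights(edge)
    out = None
    for w, prim, p in zip(weights, edge.primitives, params):
        y = w * prim(p, x)
        out = y if out is None else out + y
    return out
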