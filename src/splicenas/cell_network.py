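"""Cells as DAGs and the stacked network.

A cell has two input nodes (the outputs of the two preceding cells), four
intermediate nodes, and one output node formed by depth-concatenating the
intermediate nodes.  Normal cells preserve spatial shape; reduction cells
halve height and width by applying stride 2 on every edge that consumes a
cell input.  Reduction cells sit at ``floor(L/3)`` and ``floor(2L/3)`` of an
``L``-cell stack (no reductions for ``L < 3``) and double the per-node
channel count.

Networks come in two modes:

* ``"search"`` — every edge carries all candidate primitives, mixed by a
  shared softmax over architecture parameters (one alpha matrix for normal
  cells, one for reduction cells);
* ``"fixed"`` — every edge carries the single primitive named in a
  :class:`CellGenotype`.

The parameter containers are plain nested dicts/lists of numpy arrays so the
whole forward pass is differentiable with autograd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from . import nnops
from .search_space import PRIMITIVES, Primitive, PrimitiveSpec

DEFAULT_NODES = 4
POOL_OPS = ("max_pool_3x3", "avg_pool_3x3")


# ---------------------------------------------------------------------------
# genotype
# ---------------------------------------------------------------------------


@dataclass
class CellGenotype:
    """Discrete architecture: per node, its (primitive, predecessor) pairs.

    Predecessor indices are 0-based: 0 and 1 are the cell inputs (outputs of
    cells k-2 and k-1), 2.. are earlier intermediate nodes.  The canonical
    form has exactly two pairs per node; the per-edge derivation variant may
    keep more.
    """

    normal: list
    reduce: list
    concat: list = field(default_factory=lambda: list(range(2, 2 + DEFAULT_NODES)))
    nodes: int = DEFAULT_NODES

    def __post_init__(self):
        self.normal = [[(str(n), int(j)) for n, j in node] for node in self.normal]
        self.reduce = [[(str(n), int(j)) for n, j in node] for node in self.reduce]
        self.validate()

    def validate(self) -> None:
        for kind, part in (("normal", self.normal), ("reduce", self.reduce)):
            if len(part) != self.nodes:
                raise ValueError(f"{kind}: expected {self.nodes} node entries, got {len(part)}")
            for i, node in enumerate(part):
                if not node:
                    raise ValueError(f"{kind} node {i}: needs at least one edge")
                for name, j in node:
                    if name not in PRIMITIVES:
                        raise ValueError(f"{kind} node {i}: unknown primitive {name!r}")
                    if not 0 <= j < i + 2:
                        raise ValueError(
                            f"{kind} node {i}: predecessor index {j} out of range [0, {i + 2})"
                        )
        bad = [c for c in self.concat if not 2 <= c < self.nodes + 2]
        if bad:
            raise ValueError(f"concat indices out of range: {bad}")

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "normal": [[[n, j] for n, j in node] for node in self.normal],
            "reduce": [[[n, j] for n, j in node] for node in self.reduce],
            "concat": list(self.concat),
            "nodes": self.nodes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellGenotype":
        return cls(
            normal=[[(n, j) for n, j in node] for node in d["normal"]],
            reduce=[[(n, j) for n, j in node] for node in d["reduce"]],
            concat=list(d["concat"]),
            nodes=int(d.get("nodes", DEFAULT_NODES)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "CellGenotype":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class NetworkConfig:
    """Shape of the stacked network."""

    layers: int = 3
    init_channels: int = 16
    nodes_per_cell: int = DEFAULT_NODES
    num_classes: int = 2
    input_length: int = 141

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.init_channels < 1:
            raise ValueError("init_channels must be >= 1")
        if self.input_length < 1:
            raise ValueError("input_length must be >= 1")

    @property
    def reduction_indices(self) -> tuple:
        if self.layers < 3:
            return ()
        return (self.layers // 3, (2 * self.layers) // 3)


# ---------------------------------------------------------------------------
# node computation
# ---------------------------------------------------------------------------


def compute_node(pred_outputs: list, edge_transforms: list):
    """Elementwise sum of each transform applied to its predecessor output."""
    if not pred_outputs or len(pred_outputs) != len(edge_transforms):
        raise ValueError("need one transform per predecessor output")
    out = None
    shape = None
    for x, t in zip(pred_outputs, edge_transforms):
        y = t(x)
        if shape is None:
            shape = np.shape(y)
        elif np.shape(y) != shape:
            raise ValueError(f"edge output shape {np.shape(y)} != {shape}")
        out = y if out is None else out + y
    return out


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------


def _relu_conv_bn_init(rng, c_in, c_out):
    return {
        "w": (rng.standard_normal((c_out, c_in, 1, 1)) * np.sqrt(2.0 / c_in)).astype(np.float32),
        "gamma": np.ones(c_out, dtype=np.float32),
        "beta": np.zeros(c_out, dtype=np.float32),
    }


def _relu_conv_bn(params, x, stride=1):
    h = nnops.relu(x)
    h = nnops.conv2d(h, params["w"], stride=stride)
    return nnops.batch_norm(h, params["gamma"], params["beta"])


class Cell:
    """One cell: preprocess the two inputs to a common channel count, then
    evaluate the intermediate nodes in topological order and concatenate.

    ``entries`` is either a genotype part (fixed mode: one primitive per
    edge) or ``None`` (search mode: every possible edge with all
    ``op_names`` primitives).
    """

    def __init__(
        self,
        entries,
        kind: str,
        channels: int,
        c_prev_prev: int,
        c_prev: int,
        reduction_prev: bool = False,
        nodes: int = DEFAULT_NODES,
        concat=None,
        op_names=PRIMITIVES,
    ):
        if kind not in ("normal", "reduction"):
            raise ValueError(f"kind must be 'normal' or 'reduction', got {kind!r}")
        self.kind = kind
        self.reduction = kind == "reduction"
        self.channels = channels
        self.c_prev_prev = c_prev_prev
        self.c_prev = c_prev
        self.reduction_prev = reduction_prev
        self.nodes = nodes
        self.concat = list(range(2, nodes + 2)) if concat is None else list(concat)
        self.op_names = tuple(op_names)
        self.search_mode = entries is None

        # edge list: (node index i>=2, predecessor j, [primitives])
        self.edges = []
        if self.search_mode:
            for i in range(nodes):
                for j in range(i + 2):
                    stride = 2 if self.reduction and j < 2 else 1
                    prims = [
                        self._make_prim(name, stride) for name in self.op_names
                    ]
                    self.edges.append((i + 2, j, prims))
        else:
            if len(entries) != nodes:
                raise ValueError(f"expected {nodes} node entries, got {len(entries)}")
            for i, node in enumerate(entries):
                for name, j in node:
                    if not 0 <= j < i + 2:
                        raise ValueError(f"node {i}: predecessor index {j} out of range")
                    stride = 2 if self.reduction and j < 2 else 1
                    self.edges.append((i + 2, j, [self._make_prim(name, stride)]))
        self.out_channels = len(self.concat) * channels

    def _make_prim(self, name: str, stride: int) -> Primitive:
        spec = PrimitiveSpec(
            name=name, stride=stride, channels_in=self.channels, channels_out=self.channels
        )
        return Primitive(spec, bn_after_pool=name in POOL_OPS)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def init_params(self, rng: np.random.Generator) -> dict:
        return {
            "pre0": _relu_conv_bn_init(rng, self.c_prev_prev, self.channels),
            "pre1": _relu_conv_bn_init(rng, self.c_prev, self.channels),
            "edges": [[p.init_params(rng) for p in prims] for _, _, prims in self.edges],
        }

    def __call__(self, params: dict, s0, s1, alpha=None):
        """Forward pass.  ``alpha`` is the ``(num_edges, |O|)`` matrix in
        search mode and ignored in fixed mode."""
        s0 = _relu_conv_bn(params["pre0"], s0, stride=2 if self.reduction_prev else 1)
        s1 = _relu_conv_bn(params["pre1"], s1)
        states = [s0, s1]
        edge_outputs = {i: [] for i in range(2, self.nodes + 2)}
        for e, (i, j, prims) in enumerate(self.edges):
            # states grow in node order; edges are listed node by node, so
            # every predecessor is available when its edge is evaluated.
            x = states[j]
            if self.search_mode:
                w = nnops.softmax(alpha[e])
                y = None
                for k, prim in enumerate(prims):
                    t = w[k] * prim(params["edges"][e][k], x)
                    y = t if y is None else y + t
            else:
                y = prims[0](params["edges"][e][0], x)
            edge_outputs[i].append(y)
            if len(edge_outputs[i]) == self._in_degree(i):
                states.append(sum(edge_outputs[i][1:], edge_outputs[i][0]))
        return anp.concatenate([states[c] for c in self.concat], axis=1)

    def _in_degree(self, node: int) -> int:
        return sum(1 for i, _, _ in self.edges if i == node)


def build_cell(entries, kind, channels, c_prev_prev=None, c_prev=None, **kw) -> Cell:
    """Construct a cell transform from a genotype part (or ``None`` for a
    search-mode cell with all mixed edges)."""
    c_prev_prev = channels if c_prev_prev is None else c_prev_prev
    c_prev = channels if c_prev is None else c_prev
    return Cell(entries, kind, channels, c_prev_prev, c_prev, **kw)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class Network:
    """Stem + stacked cells + global-average-pool/linear classifier head.

    Input is ``(batch, 1, n_d, 4)``; output is ``(batch, num_classes)``
    logits.  Cell ``k`` receives the outputs of cells ``k-2`` and ``k-1``
    (both equal to the stem output for the first cell).
    """

    def __init__(self, config: NetworkConfig, genotype: CellGenotype | None = None,
                 mode: str = "fixed", op_names=PRIMITIVES):
        if mode not in ("search", "fixed"):
            raise ValueError(f"mode must be 'search' or 'fixed', got {mode!r}")
        if mode == "fixed" and genotype is None:
            raise ValueError("fixed mode requires a genotype")
        self.config = config
        self.mode = mode
        self.genotype = genotype
        self.op_names = tuple(op_names)
        reductions = set(config.reduction_indices)

        self.cells = []
        c_prev_prev = c_prev = config.init_channels
        c = config.init_channels
        reduction_prev = False
        h, w = config.input_length, 4
        for k in range(config.layers):
            red = k in reductions
            if red:
                c *= 2
            kind = "reduction" if red else "normal"
            if mode == "search":
                entries = None
            else:
                entries = genotype.reduce if red else genotype.normal
            concat = None if genotype is None else genotype.concat
            nodes = config.nodes_per_cell if genotype is None else genotype.nodes
            cell = Cell(
                entries, kind, c, c_prev_prev, c_prev,
                reduction_prev=reduction_prev, nodes=nodes, concat=concat,
                op_names=self.op_names,
            )
            self.cells.append(cell)
            c_prev_prev, c_prev = c_prev, cell.out_channels
            reduction_prev = red
            if red:
                h, w = nnops.conv_output_shape(h, w, 2)
                if h < 1 or w < 1:
                    raise ValueError(
                        f"spatial dimension reached 0 at layer {k} "
                        f"(input_length={config.input_length})"
                    )
        self.final_channels = c_prev
        self.final_spatial = (h, w)

    # -- architecture-parameter bookkeeping ---------------------------------
    @property
    def num_mixed_edges(self) -> int:
        """Edges per cell kind (search mode): sum_{i<nodes} (i+2)."""
        n = self.config.nodes_per_cell
        return n * (n + 3) // 2

    @property
    def num_ops(self) -> int:
        return len(self.op_names)

    # -- parameters ---------------------------------------------------------
    def init_params(self, seed_or_rng) -> dict:
        rng = (
            seed_or_rng
            if isinstance(seed_or_rng, np.random.Generator)
            else np.random.default_rng(seed_or_rng)
        )
        c0 = self.config.init_channels
        return {
            "stem": {
                "w": (rng.standard_normal((c0, 1, 3, 3)) * np.sqrt(2.0 / 9.0)).astype(np.float32),
                "gamma": np.ones(c0, dtype=np.float32),
                "beta": np.zeros(c0, dtype=np.float32),
            },
            "cells": [cell.init_params(rng) for cell in self.cells],
            "head": {
                "w": (
                    rng.standard_normal((self.config.num_classes, self.final_channels))
                    * np.sqrt(1.0 / self.final_channels)
                ).astype(np.float32),
                "b": np.zeros(self.config.num_classes, dtype=np.float32),
            },
        }

    # -- forward ------------------------------------------------------------
    def forward(self, params: dict, x, alphas: dict | None = None):
        if self.mode == "search" and alphas is None:
            raise ValueError("search mode requires alphas={'normal': ..., 'reduce': ...}")
        h = nnops.conv2d(x, params["stem"]["w"], stride=1)
        h = nnops.batch_norm(h, params["stem"]["gamma"], params["stem"]["beta"])
        s0 = s1 = h
        for cell, cell_params in zip(self.cells, params["cells"]):
            alpha = None
            if self.mode == "search":
                alpha = alphas["reduce"] if cell.reduction else alphas["normal"]
            s0, s1 = s1, cell(cell_params, s0, s1, alpha=alpha)
        pooled = nnops.global_avg_pool(s1)
        return nnops.linear(pooled, params["head"]["w"], params["head"]["b"])

    __call__ = forward


def build_network(genotype: CellGenotype | None, config: NetworkConfig,
                  mode: str = "fixed", op_names=PRIMITIVES) -> Network:
    """Assemble the stacked network (genotype is ignored in search mode)."""
    if mode == "search":
        return Network(config, genotype=None, mode="search", op_names=op_names)
    return Network(config, genotype=genotype, mode="fixed", op_names=op_names)


def count_parameters(params) -> int:
    """Total number of trainable scalars in a nested parameter container."""
    if isinstance(params, dict):
        return sum(count_parameters(v) for v in params.values())
    if isinstance(params, (list, tuple)):
        return sum(count_parameters(v) for v in params)
    return int(np.size(params))
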