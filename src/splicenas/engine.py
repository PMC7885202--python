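"""Bilevel architecture search.

The continuous relaxation is optimized by alternating two gradient steps per
mini-batch pair: the architecture parameters ``alpha`` take an Adam step on
the validation loss (first-order by default; an unrolled second-order
correction is available), then the network weights ``omega`` take a
momentum-SGD step on the training loss.  At the end of every epoch the
mixture is discretized into a genotype and scored by validation accuracy;
the best-scoring epoch's genotype is the search result.

All parameter containers are nested dicts/lists of numpy arrays; optimizer
updates operate on the flattened view (``autograd.misc.flatten``), which is
deterministic for a fixed container structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from autograd import grad, value_and_grad
from autograd.misc import flatten

from . import nnops
from .cell_network import CellGenotype, Network, NetworkConfig
from .search_space import PRIMITIVES, ZERO_OP
from .seqdata import SplitDataset


@dataclass
class SearchConfig:
    """Hyperparameters of the architecture search."""

    batch_size: int = 100
    epochs: int = 50
    weight_lr_init: float = 0.0025
    weight_lr_min: float = 0.001
    arch_lr: float = 0.0003
    weight_decay: float = 0.0003
    momentum: float = 0.9
    arch_weight_decay: float = 1e-3
    arch_betas: tuple = (0.9, 0.999)
    order: str = "first"  # {"first", "second"}
    derive_style: str = "top2"  # {"top2", "all_edges"}
    init_scale: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("batch_size", "weight_lr_init", "weight_lr_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.arch_lr < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if self.order not in ("first", "second"):
            raise ValueError("order must be 'first' or 'second'")


@dataclass
class EpochRecord:
    epoch: int  # 1-based
    train_loss: float
    val_loss: float
    val_accuracy: float
    genotype: CellGenotype


@dataclass
class SearchState:
    """Mutable state carried across bilevel steps."""

    network: Network
    omega: dict
    alphas: dict  # {"normal": (E, |O|), "reduce": (E, |O|)}
    w_momentum: np.ndarray | None = None
    a_moment1: np.ndarray | None = None
    a_moment2: np.ndarray | None = None
    a_step: int = 0
    lr: float = 0.0025
    train_loss: float = math.nan
    val_loss: float = math.nan
    history: list = field(default_factory=list)


@dataclass
class SearchResult:
    best_genotype: CellGenotype
    best_epoch: int
    best_val_accuracy: float
    history: list


# ---------------------------------------------------------------------------
# initialization and schedules
# ---------------------------------------------------------------------------


def init_architecture_params(num_edges: int, set_size: int, seed: int,
                             scale: float = 1e-3) -> np.ndarray:
    """Small zero-centered random alphas: initial mixture ~ uniform."""
    if num_edges < 1 or set_size < 1:
        raise ValueError("num_edges and set_size must be >= 1")
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((num_edges, set_size))


def cosine_lr(epoch: int, total_epochs: int, lr_init: float, lr_min: float) -> float:
    """Cosine annealing from ``lr_init`` (epoch 0) toward ``lr_min``."""
    t = epoch / max(total_epochs, 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + math.cos(math.pi * t))


def iterate_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield index arrays for shuffled full batches (a smaller final batch is
    kept only when it is the sole batch)."""
    perm = rng.permutation(n)
    if n <= batch_size:
        yield perm
        return
    for start in range(0, n - batch_size + 1, batch_size):
        yield perm[start : start + batch_size]


# ---------------------------------------------------------------------------
# optimizer steps on flattened containers
# ---------------------------------------------------------------------------


def sgd_momentum_step(params, grads, buf, lr, momentum, weight_decay):
    """One momentum-SGD step; returns (new_params, new_buf)."""
    p_flat, unflatten = flatten(params)
    g_flat, _ = flatten(grads)
    g_flat = g_flat + weight_decay * p_flat
    buf = momentum * buf + g_flat if buf is not None else g_flat.copy()
    return unflatten(p_flat - lr * buf), buf


def adam_step(params, grads, m, v, step, lr, betas, weight_decay, eps=1e-8):
    """One Adam step; returns (new_params, m, v, step)."""
    b1, b2 = betas
    p_flat, unflatten = flatten(params)
    g_flat, _ = flatten(grads)
    g_flat = g_flat + weight_decay * p_flat
    m = b1 * m + (1 - b1) * g_flat if m is not None else (1 - b1) * g_flat
    v = b2 * v + (1 - b2) * g_flat**2 if v is not None else (1 - b2) * g_flat**2
    step += 1
    m_hat = m / (1 - b1**step)
    v_hat = v / (1 - b2**step)
    return unflatten(p_flat - lr * m_hat / (np.sqrt(v_hat) + eps)), m, v, step


# ---------------------------------------------------------------------------
# bilevel update (generic over parameter containers)
# ---------------------------------------------------------------------------


def arch_gradient(omega, alphas, train_loss_fn, val_loss_fn, order, xi,
                  momentum_buf=None, momentum=0.0, weight_decay=0.0):
    """Gradient of the validation loss with respect to ``alphas``.

    ``train_loss_fn(omega, alphas)`` and ``val_loss_fn(omega, alphas)`` are
    scalar loss closures.  First order evaluates at the current ``omega``;
    second order takes one virtual SGD step on the training loss first and
    adds the finite-difference curvature correction.
    """
    if order == "first":
        return grad(lambda a: val_loss_fn(omega, a))(alphas)
    # second order: unroll one weight step omega' = omega - xi * g_w
    g_w = grad(lambda w: train_loss_fn(w, alphas))(omega)
    w_flat, unflat_w = flatten(omega)
    gw_flat, _ = flatten(g_w)
    gw_flat = gw_flat + weight_decay * w_flat
    if momentum_buf is not None:
        gw_flat = momentum * momentum_buf + gw_flat
    omega2 = unflat_w(w_flat - xi * gw_flat)
    g_alpha = grad(lambda a: val_loss_fn(omega2, a))(alphas)
    g_w2 = grad(lambda w: val_loss_fn(w, alphas))(omega2)
    gw2_flat, _ = flatten(g_w2)
    norm = np.linalg.norm(gw2_flat)
    if norm == 0:
        return g_alpha
    eps = 0.01 / norm
    w_plus = unflat_w(w_flat + eps * gw2_flat)
    w_minus = unflat_w(w_flat - eps * gw2_flat)
    g_a_plus = grad(lambda a: train_loss_fn(w_plus, a))(alphas)
    g_a_minus = grad(lambda a: train_loss_fn(w_minus, a))(alphas)
    ga_flat, unflat_a = flatten(g_alpha)
    gp_flat, _ = flatten(g_a_plus)
    gm_flat, _ = flatten(g_a_minus)
    return unflat_a(ga_flat - xi * (gp_flat - gm_flat) / (2 * eps))


def bilevel_update(omega, alphas, train_loss_fn, val_loss_fn, config: SearchConfig,
                   lr: float, w_momentum=None, a_m=None, a_v=None, a_step=0):
    """One alternating update of (alphas, omega).

    Returns ``(omega, alphas, w_momentum, a_m, a_v, a_step, L_train, L_val)``.
    The recorded losses are evaluated before their respective updates.
    """
    if config.order == "first":
        val_loss, g_alpha = value_and_grad(lambda a: val_loss_fn(omega, a))(alphas)
        val_loss = float(val_loss)
    else:
        val_loss = float(val_loss_fn(omega, alphas))
        g_alpha = arch_gradient(
            omega, alphas, train_loss_fn, val_loss_fn, config.order, xi=lr,
            momentum_buf=w_momentum, momentum=config.momentum,
            weight_decay=config.weight_decay,
        )
    if not math.isfinite(val_loss):
        raise FloatingPointError(f"non-finite validation loss: {val_loss}")
    alphas, a_m, a_v, a_step = adam_step(
        alphas, g_alpha, a_m, a_v, a_step, config.arch_lr,
        config.arch_betas, config.arch_weight_decay,
    )
    train_loss, g_omega = value_and_grad(lambda w: train_loss_fn(w, alphas))(omega)
    train_loss = float(train_loss)
    if not math.isfinite(train_loss):
        raise FloatingPointError(f"non-finite training loss: {train_loss}")
    omega, w_momentum = sgd_momentum_step(
        omega, g_omega, w_momentum, lr, config.momentum, config.weight_decay
    )
    return omega, alphas, w_momentum, a_m, a_v, a_step, train_loss, val_loss


def bilevel_step(state: SearchState, train_batch, val_batch, config: SearchConfig) -> SearchState:
    """One bilevel step of the search network on a (train, validation) batch
    pair; batches are ``(x, y)`` tuples."""
    xt, yt = train_batch
    xv, yv = val_batch
    if len(yt) == 0 or len(yv) == 0:
        raise ValueError("batches must be nonempty")
    net = state.network

    def train_loss_fn(omega, alphas):
        return nnops.cross_entropy(net.forward(omega, xt, alphas=alphas), yt)

    def val_loss_fn(omega, alphas):
        return nnops.cross_entropy(net.forward(omega, xv, alphas=alphas), yv)

    (omega, alphas, w_buf, a_m, a_v, a_step, l_tr, l_val) = bilevel_update(
        state.omega, state.alphas, train_loss_fn, val_loss_fn, config,
        lr=state.lr, w_momentum=state.w_momentum,
        a_m=state.a_moment1, a_v=state.a_moment2, a_step=state.a_step,
    )
    return replace(
        state, omega=omega, alphas=alphas, w_momentum=w_buf,
        a_moment1=a_m, a_moment2=a_v, a_step=a_step,
        train_loss=l_tr, val_loss=l_val,
    )


# ---------------------------------------------------------------------------
# genotype derivation
# ---------------------------------------------------------------------------


def _derive_part(alpha: np.ndarray, op_names, nodes: int, style: str):
    """Discretize one alpha matrix (edges ordered node by node, predecessors
    in increasing order)."""
    op_names = list(op_names)
    zero_idx = op_names.index(ZERO_OP) if ZERO_OP in op_names else None
    part = []
    e = 0
    for i in range(nodes):
        n_pred = i + 2
        rows = [np.asarray(nnops.softmax(alpha[e + j])) for j in range(n_pred)]
        e += n_pred
        if style == "all_edges":
            # literal per-edge argmax over the full set, zero allowed
            part.append([(op_names[int(np.argmax(r))], j) for j, r in enumerate(rows)])
            continue
        # top2: rank edges by their best non-zero-primitive weight
        candidates = []
        for j, r in enumerate(rows):
            best_p, best_w = None, -np.inf
            for p, w in enumerate(r):
                if p == zero_idx:
                    continue
                if w > best_w:  # strict: ties keep the lowest primitive index
                    best_p, best_w = p, w
            candidates.append((-best_w, best_p, j))
        candidates.sort()
        chosen = sorted(candidates[:2], key=lambda c: c[2])
        part.append([(op_names[p], j) for _, p, j in chosen])
    return part


def derive_genotype(alphas: dict, op_names=PRIMITIVES, nodes: int = 4,
                    style: str = "top2") -> CellGenotype:
    """Discretize the architecture parameters into a :class:`CellGenotype`.

    ``style="top2"`` keeps, per intermediate node, the two incoming edges
    with the largest non-zero-primitive softmax weight (each edge carrying
    its argmax non-zero primitive); ``style="all_edges"`` keeps every edge
    with its literal argmax primitive, zero included.  Ties break toward the
    lowest primitive index, then the lowest predecessor index.
    """
    if style not in ("top2", "all_edges"):
        raise ValueError("style must be 'top2' or 'all_edges'")
    for key in ("normal", "reduce"):
        if not np.all(np.isfinite(alphas[key])):
            raise ValueError(f"non-finite alpha in {key!r}")
    return CellGenotype(
        normal=_derive_part(np.asarray(alphas["normal"]), op_names, nodes, style),
        reduce=_derive_part(np.asarray(alphas["reduce"]), op_names, nodes, style),
        concat=list(range(2, nodes + 2)),
        nodes=nodes,
    )


# ---------------------------------------------------------------------------
# full search
# ---------------------------------------------------------------------------


def _accuracy(net: Network, omega, alphas, x, y, batch_size: int) -> float:
    correct = 0
    for start in range(0, len(y), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        logits = net.forward(omega, xb, alphas=alphas)
        correct += int(np.sum(np.argmax(logits, axis=1) == yb))
    return correct / len(y)


def run_search(data: SplitDataset, net_config: NetworkConfig,
               search_config: SearchConfig, op_names=PRIMITIVES,
               callback=None) -> SearchResult:
    """Run the full architecture search over ``search_config.epochs`` epochs.

    Per epoch the weight learning rate follows a cosine schedule; every
    training batch is paired with a validation batch (cycled) for the
    alternating bilevel update.  The epoch's validation accuracy and derived
    genotype are recorded; the genotype of the best epoch is returned.
    """
    if not data.train or not data.validation:
        raise ValueError("train and validation parts must be nonempty")
    xt, yt = data.arrays("train")
    xv, yv = data.arrays("validation")

    seeds = np.random.SeedSequence(search_config.seed).spawn(3)
    net = Network(net_config, mode="search", op_names=op_names)
    omega = net.init_params(np.random.default_rng(seeds[0]))
    alpha_rng = np.random.default_rng(seeds[1])
    alphas = {
        "normal": (
            search_config.init_scale
            * alpha_rng.standard_normal((net.num_mixed_edges, net.num_ops))
        ).astype(np.float32),
        "reduce": (
            search_config.init_scale
            * alpha_rng.standard_normal((net.num_mixed_edges, net.num_ops))
        ).astype(np.float32),
    }
    shuffle_rng = np.random.default_rng(seeds[2])

    state = SearchState(network=net, omega=omega, alphas=alphas)
    for epoch in range(search_config.epochs):
        state.lr = cosine_lr(
            epoch, search_config.epochs,
            search_config.weight_lr_init, search_config.weight_lr_min,
        )
        val_batches = list(iterate_minibatches(len(yv), search_config.batch_size, shuffle_rng))
        train_losses, val_losses = [], []
        v = 0
        for idx in iterate_minibatches(len(yt), search_config.batch_size, shuffle_rng):
            vidx = val_batches[v % len(val_batches)]
            v += 1
            state = bilevel_step(
                state, (xt[idx], yt[idx]), (xv[vidx], yv[vidx]), search_config
            )
            train_losses.append(state.train_loss)
            val_losses.append(state.val_loss)
        acc = _accuracy(net, state.omega, state.alphas, xv, yv, search_config.batch_size)
        genotype = derive_genotype(
            state.alphas, op_names=op_names, nodes=net_config.nodes_per_cell,
            style=search_config.derive_style,
        )
        record = EpochRecord(
            epoch=epoch + 1,
            train_loss=float(np.mean(train_losses)),
            val_loss=float(np.mean(val_losses)),
            val_accuracy=acc,
            genotype=genotype,
        )
        state.history.append(record)
        if callback is not None:
            callback(record)

    best = max(state.history, key=lambda r: r.val_accuracy)
    return SearchResult(
        best_genotype=best.genotype,
        best_epoch=best.epoch,
        best_val_accuracy=best.val_accuracy,
        history=state.history,
    )


def write_history_tsv(history: list, path) -> None:
    """Write the per-epoch search history as a TSV."""
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\tval_accuracy\n")
        for r in history:
            fh.write(f"{r.epoch}\t{r.train_loss:.6f}\t{r.val_loss:.6f}\t{r.val_accuracy:.6f}\n")
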