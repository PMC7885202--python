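"""Fixed-architecture training, the binary-classification metric suite, and
the cross-dataset transfer trimming rule."""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from autograd import value_and_grad
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve

from . import nnops
from .cell_network import CellGenotype, Network, NetworkConfig, count_parameters
from .engine import cosine_lr, iterate_minibatches, sgd_momentum_step
from .seqdata import DNASequence, SplitDataset, to_arrays


@dataclass
class TrainConfig:
    """Hyperparameters for retraining a derived (fixed) architecture.

    The optimizer settings mirror the weight side of the search: momentum
    SGD with cosine-annealed learning rate and cross-entropy loss.
    """

    epochs: int = 70
    batch_size: int = 100
    lr_init: float = 0.0025
    lr_min: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0003
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")


@dataclass
class EvalMetrics:
    """Threshold metrics at 0.5 plus ranking metrics and curve points.

    A metric whose denominator is empty (e.g. sensitivity with no positive
    labels) is NaN and listed in ``undefined``.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    auc: float
    confusion: tuple  # (TP, FP, TN, FN)
    roc_points: list = field(default_factory=list)
    pr_points: list = field(default_factory=list)
    threshold: float = 0.5
    undefined: tuple = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_score": self.f_score,
            "auc": self.auc,
        }


@dataclass
class TrainedModel:
    network: Network
    params: dict
    genotype: CellGenotype
    net_config: NetworkConfig
    train_config: TrainConfig
    history: list = field(default_factory=list)  # (epoch, train_loss, val_loss)

    def num_parameters(self) -> int:
        return count_parameters(self.params)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_fixed(genotype: CellGenotype, data: SplitDataset,
                net_config: NetworkConfig, train_config: TrainConfig,
                callback=None) -> TrainedModel:
    """Train the fixed network for ``train_config.epochs`` epochs of
    momentum SGD on cross-entropy; fully deterministic given the seed."""
    if not data.train:
        raise ValueError("train part must be nonempty")
    xt, yt = data.arrays("train")
    net = Network(net_config, genotype=genotype, mode="fixed")
    seeds = np.random.SeedSequence(train_config.seed).spawn(2)
    params = net.init_params(np.random.default_rng(seeds[0]))
    shuffle_rng = np.random.default_rng(seeds[1])

    has_val = bool(data.validation)
    if has_val:
        xv, yv = data.arrays("validation")

    buf = None
    history = []
    for epoch in range(train_config.epochs):
        lr = cosine_lr(epoch, train_config.epochs, train_config.lr_init, train_config.lr_min)
        losses = []
        for idx in iterate_minibatches(len(yt), train_config.batch_size, shuffle_rng):
            xb, yb = xt[idx], yt[idx]

            def loss_fn(p):
                return nnops.cross_entropy(net.forward(p, xb), yb)

            loss, g = value_and_grad(loss_fn)(params)
            loss = float(loss)
            if not math.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch + 1}")
            params, buf = sgd_momentum_step(
                params, g, buf, lr, train_config.momentum, train_config.weight_decay
            )
            losses.append(loss)
        val_loss = math.nan
        if has_val:
            val_loss = float(
                nnops.cross_entropy(net.forward(params, xv), yv)
            )
        record = (epoch + 1, float(np.mean(losses)), val_loss)
        history.append(record)
        if callback is not None:
            callback(record)
    return TrainedModel(
        network=net, params=params, genotype=genotype,
        net_config=net_config, train_config=train_config, history=history,
    )


def predict_scores(model: TrainedModel, x: np.ndarray, batch_size: int = 100) -> np.ndarray:
    """Class-1 probabilities, computed batch-wise (batch normalization uses
    the statistics of each scoring batch)."""
    scores = []
    for start in range(0, len(x), batch_size):
        logits = model.network.forward(model.params, x[start : start + batch_size])
        scores.append(nnops.softmax(logits, axis=1)[:, 1])
    return np.concatenate(scores)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _safe_div(num, den):
    return num / den if den > 0 else math.nan


def compute_metrics(labels, scores, threshold: float = 0.5) -> EvalMetrics:
    """Metric suite for binary labels and real scores.

    AUC is the probability that a random positive outranks a random
    negative, with ties counted half (midrank statistic — equivalent to
    trapezoidal ROC integration).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {scores.shape} scores")
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")

    preds = scores >= threshold
    tp = int(np.sum(preds & (labels == 1)))
    fp = int(np.sum(preds & (labels == 0)))
    tn = int(np.sum(~preds & (labels == 0)))
    fn = int(np.sum(~preds & (labels == 1)))
    n_pos, n_neg = tp + fn, tn + fp

    accuracy = (tp + tn) / labels.size
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f_score = math.nan
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)

    if n_pos > 0 and n_neg > 0:
        ranks = rankdata(scores)  # midranks
        auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        fpr, tpr, _ = roc_curve(labels, scores)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        prec, rec, _ = precision_recall_curve(labels, scores)
        pr_points = list(zip(rec.tolist(), prec.tolist()))
    else:
        warnings.warn("single-class input: AUC and curves are undefined", stacklevel=2)
        auc = math.nan
        roc_points, pr_points = [], []

    undefined = tuple(
        name
        for name, value in (
            ("sensitivity", sensitivity), ("specificity", specificity),
            ("f_score", f_score), ("auc", auc),
        )
        if isinstance(value, float) and math.isnan(value)
    )
    return EvalMetrics(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        f_score=f_score, auc=auc, confusion=(tp, fp, tn, fn),
        roc_points=roc_points, pr_points=pr_points,
        threshold=threshold, undefined=undefined,
    )


def evaluate_model(model: TrainedModel, test_set, threshold: float = 0.5,
                   batch_size: int = 100) -> EvalMetrics:
    """Score a held-out test set (a list of encoded sequences or an
    ``(x, y)`` tuple) and compute the metric suite."""
    if isinstance(test_set, tuple):
        x, y = test_set
    else:
        if not test_set:
            raise ValueError("test set is empty")
        x, y = to_arrays(test_set)
    scores = predict_scores(model, x, batch_size=batch_size)
    return compute_metrics(y, scores, threshold=threshold)


# ---------------------------------------------------------------------------
# transfer trimming
# ---------------------------------------------------------------------------


def trim_for_transfer(seq: DNASequence, source_site_offset: int,
                      target_length: int, target_site_offset: int) -> DNASequence:
    """Cut a window of ``target_length`` bases so the splice dimer moves from
    ``source_site_offset`` to ``target_site_offset``.  Pure slicing: if the
    window exceeds the sequence bounds an error is raised (no padding)."""
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    if not 0 <= source_site_offset < len(seq.bases):
        raise ValueError(f"source site offset {source_site_offset} out of bounds")
    if not 0 <= target_site_offset < target_length:
        raise ValueError(f"target site offset {target_site_offset} out of bounds")
    start = source_site_offset - target_site_offset
    end = start + target_length
    if start < 0 or end > len(seq.bases):
        raise ValueError(
            f"window [{start}, {end}) exceeds sequence bounds [0, {len(seq.bases)}); "
            "padding is not supported"
        )
    return DNASequence(id=seq.id, bases=seq.bases[start:end], label=seq.label)


# ---------------------------------------------------------------------------
# persistence and reports
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, prefix) -> None:
    """Save weights (``<prefix>.npz``) and architecture (``<prefix>.json``)."""
    from autograd.misc import flatten

    flat, _ = flatten(model.params)
    np.savez(f"{prefix}.npz", theta=flat)
    meta = {
        "genotype": model.genotype.to_dict(),
        "net_config": {
            "layers": model.net_config.layers,
            "init_channels": model.net_config.init_channels,
            "nodes_per_cell": model.net_config.nodes_per_cell,
            "num_classes": model.net_config.num_classes,
            "input_length": model.net_config.input_length,
        },
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def load_model(prefix) -> TrainedModel:
    from autograd.misc import flatten

    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    genotype = CellGenotype.from_dict(meta["genotype"])
    net_config = NetworkConfig(**meta["net_config"])
    net = Network(net_config, genotype=genotype, mode="fixed")
    template = net.init_params(0)
    _, unflatten = flatten(template)
    theta = np.load(f"{prefix}.npz")["theta"]
    return TrainedModel(
        network=net, params=unflatten(theta), genotype=genotype,
        net_config=net_config, train_config=TrainConfig(),
    )


def write_metrics_tsv(metrics_list, path) -> None:
    """Write metrics as TSV (metric, mean, sd) over one or more repeats."""
    rows = {}
    for name in ("accuracy", "sensitivity", "specificity", "f_score", "auc"):
        values = np.array([m.as_dict()[name] for m in metrics_list], dtype=float)
        rows[name] = (np.nanmean(values), np.nanstd(values))
    with open(path, "w") as fh:
        fh.write("metric\tmean\tsd\n")
        for name, (mean, sd) in rows.items():
            fh.write(f"{name}\t{mean:.6f}\t{sd:.6f}\n")


def write_curve_tsv(points, path, xlabel: str, ylabel: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{xlabel}\t{ylabel}\n")
        for x, y in points:
            fh.write(f"{x:.6f}\t{y:.6f}\n")
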