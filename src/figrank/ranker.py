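"""Listwise learning-to-rank core.

The model is a linear scorer f_w(x) = w.x over figure feature vectors.  A
list of scores induces a Plackett–Luce permutation distribution; training
minimises the cross entropy between the distributions induced by the gold
scores (reciprocal dense ranks) and the model scores.  Two losses are
provided: the classic top-1 marginal (ListNet) and the extended top-2
marginal over the n(n-1) ordered figure pairs, which captures strictly more
of the permutation structure and is tractable because articles rarely have
more than ~9 figures.

Gradient descent uses per-article updates in a fixed dataset order, with an
adaptive learning rate: after every epoch the configured training metric is
evaluated and, if it improved or stayed equal while the rate is above a
floor, the rate is multiplied by 0.875 (the rule is also available in the
more conventional decay-on-non-improvement direction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .corpus import GoldRanking

__all__ = [
    "RankingInstance",
    "TrainerConfig",
    "Ranking",
    "FigureRanker",
    "FigureRankerResults",
    "score",
    "gold_scores",
    "top1_distribution",
    "top2_distribution",
    "loss_top1",
    "loss_top2",
    "gradient",
    "train",
    "predict_ranking",
]


@dataclass
class RankingInstance:
    """One article's list: feature vectors, gold scores and dense gold ranks."""

    article_id: str
    features: np.ndarray  # (n_figures, n_features)
    gold_ranks: np.ndarray  # dense, min 1

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.gold_ranks = np.asarray(self.gold_ranks, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        if len(self.gold_ranks) != self.features.shape[0]:
            raise ValueError("one gold rank per figure required")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Ground-truth scores: reciprocal of the dense gold rank."""
        return 1.0 / self.gold_ranks


@dataclass
class TrainerConfig:
    learning_rate: float = 0.0009
    iterations: int = 200
    lr_decay_factor: float = 0.875
    lr_floor: float = 1e-6
    loss_mode: Literal["top1", "top2"] = "top2"
    seed: int = 0
    #: metric driving the adaptive rule: "wer_rk", "ndcg", "wer_fr", or
    #: "loss" (negated total loss; cheaper, no ranking pass)
    training_metric: str = "wer_rk"
    decay_on: Literal["improvement", "non_improvement"] = "improvement"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class Ranking:
    """A predicted order: system ranks (permutation of 1..n) per figure."""

    article_id: str
    scores: np.ndarray
    system_ranks: np.ndarray


def score(w: np.ndarray, x: np.ndarray) -> float:
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    if w.shape != x.shape:
        raise ValueError(f"dimension mismatch: {w.shape} vs {x.shape}")
    return float(w @ x)


def gold_scores(gold: GoldRanking | Sequence[int]) -> np.ndarray:
    ranks = np.asarray(gold.ranks if isinstance(gold, GoldRanking) else gold, float)
    return 1.0 / ranks


def top1_distribution(z: np.ndarray) -> np.ndarray:
    """P(figure j ranked first) — softmax of the scores, overflow-safe."""
    z = np.asarray(z, float)
    if z.size < 1:
        raise ValueError("need at least one score")
    shifted = z - z.max()
    e = np.exp(shifted)
    return e / e.sum()


def top2_distribution(z: np.ndarray) -> np.ndarray:
    """P(ordered pair (j,k) occupies the first two ranks), as an n x n matrix.

    P(j,k) = p_j * p_k / (1 - p_j) for j != k with p the top-1 distribution;
    the diagonal is zero and the off-diagonal entries sum to 1.
    """
    z = np.asarray(z, float)
    n = z.size
    if n < 2:
        raise ValueError("top-2 distribution needs n >= 2; use top1 mode")
    p = top1_distribution(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.outer(p / (1.0 - p), p)
    np.fill_diagonal(P, 0.0)
    return P


def _log_top1(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, float)
    return z - logsumexp(z)


def loss_top1(y: np.ndarray, z: np.ndarray) -> float:
    """Cross entropy between the top-1 distributions of y and z."""
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if y.shape != z.shape:
        raise ValueError("y and z must have equal length")
    return float(-(top1_distribution(y) * _log_top1(z)).sum())


def _log_top2(z: np.ndarray) -> np.ndarray:
    """log P(j,k) matrix (diagonal = -inf, never selected by callers)."""
    lp = _log_top1(z)
    p = np.exp(lp)
    with np.errstate(divide="ignore"):
        log_rest = np.log1p(-p)  # log(1 - p_j)
    L = lp[:, None] - log_rest[:, None] + lp[None, :]
    np.fill_diagonal(L, -np.inf)
    return L


def loss_top2(y: np.ndarray, z: np.ndarray) -> float:
    """Cross entropy between the top-2 pair distributions of y and z."""
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if y.shape != z.shape:
        raise ValueError("y and z must have equal length")
    A = top2_distribution(y)
    L = _log_top2(z)
    mask = ~np.eye(len(y), dtype=bool)
    return float(-(A[mask] * L[mask]).sum())


def _grad_z_top1(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    return top1_distribution(z) - top1_distribution(y)


def _grad_z_top2(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    A = top2_distribution(y)
    p = top1_distribution(z)
    rowA = A.sum(axis=1)
    colA = A.sum(axis=0)
    inv = rowA / (1.0 - p)
    c = inv.sum()
    return p - rowA - colA + p * (c - inv)


def gradient(
    loss_mode: str, X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Analytic gradient of the listwise loss with respect to w."""
    X = np.asarray(X, float)
    z = X @ w
    if loss_mode == "top1":
        gz = _grad_z_top1(y, z)
    elif loss_mode == "top2":
        gz = _grad_z_top2(y, z)
    else:
        raise ValueError(f"unknown loss mode {loss_mode!r}")
    return X.T @ gz


def predict_ranking(w: np.ndarray, instance: RankingInstance) -> Ranking:
    """Rank figures by descending score; exact ties break by position."""
    scores = instance.features @ np.asarray(w, float)
    order = np.lexsort((np.arange(instance.n), -scores))
    ranks = np.empty(instance.n, dtype=int)
    ranks[order] = np.arange(1, instance.n + 1)
    return Ranking(instance.article_id, scores, ranks)


@dataclass
class _Scaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, dataset: Sequence[RankingInstance]) -> "_Scaler":
        stacked = np.vstack([inst.features for inst in dataset])
        mean = stacked.mean(axis=0)
        std = stacked.std(axis=0)
        std[std == 0.0] = 1.0
        return cls(mean, std)

    def apply(self, inst: RankingInstance) -> RankingInstance:
        return RankingInstance(
            inst.article_id, (inst.features - self.mean) / self.std, inst.gold_ranks
        )

    @classmethod
    def identity(cls, dim: int) -> "_Scaler":
        return cls(np.zeros(dim), np.ones(dim))


def _training_metric(
    w: np.ndarray, dataset: Sequence[RankingInstance], metric: str
) -> float:
    from . import metrics as metrics_mod

    fn = metrics_mod.similarity_metric(metric)
    vals = [
        fn(predict_ranking(w, inst).system_ranks, inst.gold_ranks)
        for inst in dataset
    ]
    return float(np.mean(vals))


def _total_loss(
    w: np.ndarray, dataset: Sequence[RankingInstance], loss_mode: str
) -> float:
    total = 0.0
    for inst in dataset:
        if loss_mode == "top2" and inst.n < 2:
            continue
        z = inst.features @ w
        total += loss_top1(inst.y, z) if loss_mode == "top1" else loss_top2(inst.y, z)
    return total


def train(
    dataset: Sequence[RankingInstance],
    config: TrainerConfig,
    callback: Callable[[int, float, float, float], None] | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Gradient-descent training; returns (w, per-iteration trace).

    One iteration = one pass over the articles in fixed order with a
    per-article update w <- w - r * grad.  Articles with a single figure are
    skipped under the top-2 loss (their ranking is trivial) and contribute a
    zero gradient under top-1.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    dim = dataset[0].features.shape[1]
    for inst in dataset:
        if inst.features.shape[1] != dim:
            raise ValueError("inconsistent feature dimension across instances")
    w = np.zeros(dim)
    r = config.learning_rate
    trace: list[dict] = []
    prev_metric = None
    for it in range(1, config.iterations + 1):
        for inst in dataset:
            if config.loss_mode == "top2" and inst.n < 2:
                continue
            g = gradient(config.loss_mode, inst.features, inst.y, w)
            w = w - r * g
        loss = _total_loss(w, dataset, config.loss_mode)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at iteration {it} (lr={r:g}); "
                "reduce the learning rate or standardize features"
            )
        if config.training_metric == "loss":
            metric = -loss
        else:
            metric = _training_metric(w, dataset, config.training_metric)
        improved_or_equal = prev_metric is None or metric >= prev_metric
        decay = improved_or_equal if config.decay_on == "improvement" else not improved_or_equal
        if decay and r > config.lr_floor:
            r *= config.lr_decay_factor
        prev_metric = metric
        trace.append({"iteration": it, "loss": loss, "metric": metric, "lr": r})
        if callback is not None:
            callback(it, loss, metric, r)
    return w, trace


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------


class FigureRanker:
    """Linear listwise ranking model over a set of article lists.

    Parameters
    ----------
    dataset:
        Training lists (one per article).
    config:
        Trainer configuration; ``loss_mode`` selects the top-1 (ListNet) or
        the extended top-2 loss.
    feature_names:
        Optional registry naming the feature columns.
    """

    def __init__(
        self,
        dataset: Sequence[RankingInstance],
        config: TrainerConfig | None = None,
        feature_names: Sequence[str] | None = None,
    ):
        self.dataset = list(dataset)
        self.config = config or TrainerConfig()
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i}" for i in range(1, self.dataset[0].features.shape[1] + 1)]
        )

    @classmethod
    def from_feature_matrix(cls, matrix, config: TrainerConfig | None = None):
        """Build from a :class:`figrank.features.FeatureMatrix`."""
        dataset = [
            RankingInstance(aid, X, ranks) for aid, (X, ranks) in matrix.as_arrays().items()
        ]
        return cls(dataset, config=config, feature_names=matrix.registry)

    def fit(self) -> "FigureRankerResults":
        if self.config.standardize:
            scaler = _Scaler.fit(self.dataset)
        else:
            scaler = _Scaler.identity(len(self.feature_names))
        scaled = [scaler.apply(inst) for inst in self.dataset]
        w, trace = train(scaled, self.config)
        return FigureRankerResults(self, w, scaler, trace)


class FigureRankerResults:
    """Fitted weights plus the training trace and prediction helpers."""

    def __init__(
        self,
        model: FigureRanker,
        params: np.ndarray,
        scaler: _Scaler,
        trace: list[dict],
    ):
        self.model = model
        self.params = np.asarray(params, float)
        self.scaler = scaler
        self.trace = trace

    def predict(self, instance: RankingInstance) -> Ranking:
        return predict_ranking(self.params, self.scaler.apply(instance))

    def predict_many(self, instances: Sequence[RankingInstance]) -> list[Ranking]:
        return [self.predict(inst) for inst in instances]

    @property
    def final_loss(self) -> float:
        return self.trace[-1]["loss"] if self.trace else float("nan")

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Listwise figure ranking model",
            "=" * 34,
            f"loss mode:        {cfg.loss_mode}",
            f"articles:         {len(self.model.dataset)}",
            f"features:         {len(self.model.feature_names)}",
            f"iterations:       {len(self.trace)}",
            f"final loss:       {self.final_loss:.6f}",
            f"final train ~WER-RK: {self.trace[-1]['metric']:.4f}" if self.trace else "",
            f"final lr:         {self.trace[-1]['lr']:.3g}" if self.trace else "",
            "",
            "largest |weights|:",
        ]
        order = np.argsort(-np.abs(self.params))[:10]
        for i in order:
            lines.append(f"  {self.model.feature_names[i]:<34s} {self.params[i]:+.4f}")
        return "\n".join(line for line in lines if line is not None)

    def save(self, path: str | Path) -> None:
        cfg = self.model.config
        payload = {
            "feature_names": self.model.feature_names,
            "weights": self.params.tolist(),
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_std": self.scaler.std.tolist(),
            "config": {
                "learning_rate": cfg.learning_rate,
                "iterations": cfg.iterations,
                "lr_decay_factor": cfg.lr_decay_factor,
                "lr_floor": cfg.lr_floor,
                "loss_mode": cfg.loss_mode,
                "seed": cfg.seed,
                "training_metric": cfg.training_metric,
                "decay_on": cfg.decay_on,
                "standardize": cfg.standardize,
            },
            "trace": self.trace,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FigureRankerResults":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        config = TrainerConfig(**payload["config"])
        model = FigureRanker.__new__(FigureRanker)
        model.dataset = []
        model.config = config
        model.feature_names = payload["feature_names"]
        scaler = _Scaler(
            np.asarray(payload["scaler_mean"], float),
            np.asarray(payload["scaler_std"], float),
        )
        return cls(model, np.asarray(payload["weights"], float), scaler, payload["trace"])
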