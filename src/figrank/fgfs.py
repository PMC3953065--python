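"""Forward greedy feature selection (FGFS).

Starting from the empty set, each iteration evaluates every unselected
feature appended to the current set under an evaluation protocol (by
default, article-level k-fold cross-validation of the listwise trainer)
and adds the feature with the best score, breaking ties toward the lowest
registry index.  The output records the best score (opt), the iteration it
was reached (iter) and the selected prefix, plus a full audit log of every
candidate evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .metrics import similarity_metric
from .ranker import FigureRanker, RankingInstance, TrainerConfig


@dataclass
class FGFSResult:
    selected: list[str]  # in selection order
    per_iteration_best: list[float]
    opt: float
    opt_iteration: int  # 1-based iteration index of the best prefix
    audit: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def best_prefix(self) -> list[str]:
        return self.selected[: self.opt_iteration]

    def write_audit(self, path: str | Path) -> None:
        lines = ["iteration\tcandidate\tscore"]
        lines += [f"{it}\t{name}\t{score:.6f}" for it, name, score in self.audit]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _restrict(dataset: Sequence[RankingInstance], cols: Sequence[int]) -> list[RankingInstance]:
    cols = list(cols)
    return [
        RankingInstance(inst.article_id, inst.features[:, cols], inst.gold_ranks)
        for inst in dataset
    ]


def kfold_protocol(
    dataset: Sequence[RankingInstance],
    metric: str = "wer_rk",
    trainer_config: TrainerConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> Callable[[Sequence[int]], float]:
    """Default evaluation protocol: seeded article-level k-fold CV.

    Returns a callable mapping a feature-column subset to the mean held-out
    metric over the folds.
    """
    config = trainer_config or TrainerConfig()
    fn = similarity_metric(metric)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(dataset))
    n_folds = min(n_folds, len(dataset))
    folds = np.array_split(idx, n_folds)

    def protocol(cols: Sequence[int]) -> float:
        sub = _restrict(dataset, cols)
        scores = []
        for fold in folds:
            test_ids = set(int(i) for i in fold)
            train_set = [inst for i, inst in enumerate(sub) if i not in test_ids]
            test_set = [sub[i] for i in sorted(test_ids)]
            if not train_set or not test_set:
                continue
            results = FigureRanker(train_set, config=config).fit()
            for inst in test_set:
                pred = results.predict(inst)
                scores.append(fn(pred.system_ranks, inst.gold_ranks))
        return float(np.mean(scores))

    return protocol


def _check_dataset(dataset: Sequence[RankingInstance]) -> None:
    if not dataset:
        raise ValueError("empty dataset")
    if all(len(set(inst.gold_ranks.tolist())) == 1 for inst in dataset):
        raise ValueError("degenerate dataset: every gold ranking is trivial")


def fgfs(
    dataset: Sequence[RankingInstance],
    feature_names: Sequence[str],
    metric: str = "wer_rk",
    eval_protocol: Callable[[Sequence[int]], float] | None = None,
    trainer_config: TrainerConfig | None = None,
    patience: int = 10,
    max_features: int | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> FGFSResult:
    """Greedy forward selection over the feature registry."""
    _check_dataset(dataset)
    n_feat = dataset[0].features.shape[1]
    if n_feat < 2:
        raise ValueError("need at least two features in the registry")
    if len(feature_names) != n_feat:
        raise ValueError("feature_names must match the feature dimension")
    protocol = eval_protocol or kfold_protocol(
        dataset, metric=metric, trainer_config=trainer_config, n_folds=n_folds, seed=seed
    )
    limit = max_features if max_features is not None else n_feat

    selected: list[int] = []
    best_scores: list[float] = []
    audit: list[tuple[int, str, float]] = []
    opt = -np.inf
    opt_iter = 0
    stall = 0
    it = 0
    while len(selected) < min(limit, n_feat):
        it += 1
        best_candidate = None
        best_score = -np.inf
        for c in range(n_feat):
            if c in selected:
                continue
            score = protocol(selected + [c])
            audit.append((it, feature_names[c], score))
            if score > best_score:  # strict: ties keep the lowest index
                best_score = score
                best_candidate = c
        selected.append(best_candidate)
        best_scores.append(best_score)
        if best_score > opt:
            opt = best_score
            opt_iter = it
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return FGFSResult(
        selected=[feature_names[c] for c in selected],
        per_iteration_best=best_scores,
        opt=float(opt),
        opt_iteration=opt_iter,
        audit=audit,
    )


def select_top_individual(
    dataset: Sequence[RankingInstance],
    feature_names: Sequence[str],
    count: int,
    metric: str = "wer_rk",
    eval_protocol: Callable[[Sequence[int]], float] | None = None,
    trainer_config: TrainerConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """Top `count` features by their individual score under the protocol."""
    _check_dataset(dataset)
    n_feat = dataset[0].features.shape[1]
    if count > n_feat:
        raise ValueError("count exceeds registry size")
    protocol = eval_protocol or kfold_protocol(
        dataset, metric=metric, trainer_config=trainer_config, n_folds=n_folds, seed=seed
    )
    scored = [(-protocol([c]), c) for c in range(n_feat)]
    scored.sort()  # ties keep the lowest registry index
    return [feature_names[c] for _, c in scored[:count]]


def combine_fgfs_sets(
    results: Sequence[FGFSResult], registry: Sequence[str]
) -> list[str]:
    """Set union of the selected features, in registry order."""
    if not results:
        raise ValueError("need at least one FGFS result")
    union = set()
    for res in results:
        union.update(res.best_prefix)
    return [name for name in registry if name in union]
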