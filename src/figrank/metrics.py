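"""Ranking-quality metrics for figure ranking.

Three article-level metrics are provided, each reported in its
"similarity" form (1 - error) so larger is better:

* ``wer_rk`` — a weighted pairwise error rate.  Every discordant
  reference/system pair is penalised by the product of an importance weight
  of the pair's better *reference* rank and the same weight of its better
  *system* rank, normalised by the weight mass of a perfect ranking, so
  mistakes involving important figures placed at prominent positions cost
  the most.  Reference-tied pairs are never error pairs.
* ``ndcg`` — discounted cumulative gain with reciprocal-rank gain,
  normalised so the ideal ordering scores exactly 1.
* ``wer_fr`` — the displacement of the human-top figure, (s(x1) - 1)/(m - 1),
  using the best system rank within a tied top group.

The default importance weight is the steep geometric scheme
w(r) = 2^(-r(r-1)/2) (w(1)=1, w(2)=1/2, w(3)=1/8, ...), calibrated so that
the exact expectation of 1-WER-RK over uniformly random permutations
reproduces the metric's published behaviour on strict references
(0.5 at m=2 and 29/54 = 0.537 at m=3 exactly).  A "reciprocal" scheme
(w(r)=1/r, the same currency as the gold ground-truth scores) is available.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import GoldRanking

WeightScheme = str  # "geometric" | "reciprocal"

DEFAULT_WEIGHTS: WeightScheme = "geometric"

_EXACT_LIMIT = 9  # m! enumeration cap


def rank_weight(rank: int, scheme: WeightScheme = DEFAULT_WEIGHTS) -> float:
    """Importance weight of a (1-based) rank; decreasing, w(1) = 1."""
    if rank < 1:
        raise ValueError("ranks are 1-based")
    if scheme == "geometric":
        return 2.0 ** (-(rank * (rank - 1)) // 2)
    if scheme == "reciprocal":
        return 1.0 / rank
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _as_ranks(x) -> np.ndarray:
    a = np.asarray(x, dtype=int)
    if a.ndim != 1:
        raise ValueError("rank vectors must be 1-D")
    return a


def wer_rk(
    system: Sequence[int],
    reference: Sequence[int],
    weights: WeightScheme = DEFAULT_WEIGHTS,
) -> float:
    """Weighted pairwise error rate in [0, 1] (0 = perfect agreement).

    Error mass = sum over discordant non-tied pairs of
    w(min reference rank) * w(min system rank); the normaliser is the total
    pair weight mass w(min reference rank)^2 over all pairs, i.e. the mass a
    maximally wrong top-aligned ranking could accrue.  Bounded by 1 via
    Cauchy-Schwarz.
    """
    s = _as_ranks(system)
    r = _as_ranks(reference)
    if s.shape != r.shape:
        raise ValueError("system and reference must have equal length")
    m = len(s)
    if m < 2:
        return 0.0
    jj, kk = np.triu_indices(m, k=1)
    w_of = np.array([rank_weight(v, weights) for v in range(1, m + 1)])
    wr = w_of[np.minimum(r[jj], r[kk]) - 1]
    ws = w_of[np.minimum(s[jj], s[kk]) - 1]
    discordant = (s[jj] - s[kk]) * (r[jj] - r[kk]) < 0  # tied refs never error
    den = float((wr * wr).sum())
    if den == 0.0:
        return 0.0
    num = float((wr * ws)[discordant].sum())
    return num / den


def ndcg(system: Sequence[int], reference: Sequence[int]) -> float:
    """Normalised discounted cumulative gain in (0, 1]; 1 for the ideal order.

    Gain of a figure is the reciprocal of its reference rank; the discount at
    system position k is 1/log2(k+1); the normaliser is the DCG of the
    reference ordering itself.
    """
    s = _as_ranks(system)
    r = _as_ranks(reference)
    if s.shape != r.shape:
        raise ValueError("system and reference must have equal length")
    m = len(s)
    if m == 1:
        return 1.0
    order = np.argsort(s)  # figures by system position
    gains = 1.0 / r[order]
    discounts = 1.0 / np.log2(np.arange(2, m + 2))
    dcg = float(gains @ discounts)
    ideal_gains = np.sort(1.0 / r)[::-1]
    idcg = float(ideal_gains @ discounts)
    return dcg / idcg


def wer_fr(system: Sequence[int], reference: Sequence[int]) -> float:
    """Displacement error of the most important figure, in [0, 1].

    (s(x1) - 1) / (m - 1) where s(x1) is the best system rank among the
    figures the reference places at rank 1.
    """
    s = _as_ranks(system)
    r = _as_ranks(reference)
    if s.shape != r.shape:
        raise ValueError("system and reference must have equal length")
    m = len(s)
    if m == 1:
        return 0.0
    top = s[r == r.min()]
    return float(top.min() - 1) / (m - 1)


def tie_pair_percentage(reference: Sequence[int]) -> float:
    """Fraction of figure pairs annotated equally important."""
    r = _as_ranks(reference)
    m = len(r)
    if m < 2:
        return 0.0
    ties = sum(1 for j, k in itertools.combinations(range(m), 2) if r[j] == r[k])
    return ties / (m * (m - 1) / 2)


# -- similarity (larger-is-better) forms ------------------------------------


def sim_wer_rk(system, reference, weights: WeightScheme = DEFAULT_WEIGHTS) -> float:
    return 1.0 - wer_rk(system, reference, weights)


def sim_wer_fr(system, reference) -> float:
    return 1.0 - wer_fr(system, reference)


_METRICS: dict[str, Callable] = {
    "wer_rk": sim_wer_rk,
    "ndcg": ndcg,
    "wer_fr": sim_wer_fr,
}


def similarity_metric(name: str) -> Callable[[Sequence[int], Sequence[int]], float]:
    """Look up a larger-is-better metric by name (wer_rk, ndcg, wer_fr)."""
    try:
        return _METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; choose from {sorted(_METRICS)}")


def random_expectation(
    metric: str | Callable,
    reference: Sequence[int],
    mode: str = "exact",
    repeats: int = 100,
    seed: int | None = None,
) -> float:
    """Expected metric value under a uniformly random system permutation.

    ``exact`` enumerates all m! permutations (m <= 9); ``sampled`` averages
    over ``repeats`` uniformly drawn permutations, matching the 100-trial
    random baseline.
    """
    fn = similarity_metric(metric) if isinstance(metric, str) else metric
    r = _as_ranks(reference)
    m = len(r)
    if m < 2:
        raise ValueError("need at least two figures")
    if mode == "exact":
        if m > _EXACT_LIMIT:
            raise ValueError(
                f"exact enumeration is limited to m <= {_EXACT_LIMIT}; use mode='sampled'"
            )
        total = 0.0
        count = 0
        for perm in itertools.permutations(range(1, m + 1)):
            total += fn(np.array(perm), r)
            count += 1
        return total / count
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        total = 0.0
        for _ in range(repeats):
            total += fn(rng.permutation(m) + 1, r)
        return total / repeats
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Dataset-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Per-article metric values with mean +/- population std summaries."""

    per_article: dict[str, dict[str, float]]
    by_figure_count: dict[int, dict[str, float]] = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        vals = [row[metric] for row in self.per_article.values()]
        return float(np.mean(vals))

    def std(self, metric: str) -> float:
        vals = [row[metric] for row in self.per_article.values()]
        return float(np.std(vals))  # population std

    def summary(self) -> dict[str, str]:
        return {
            name: f"{self.mean(name):.3f}±{self.std(name):.3f}"
            for name in _METRICS
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_article": self.per_article,
            "summary": {
                name: {"mean": self.mean(name), "std": self.std(name)}
                for name in _METRICS
            },
            "by_figure_count": self.by_figure_count,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        names = list(_METRICS)
        lines = ["article_id\t" + "\t".join(names)]
        for aid, row in self.per_article.items():
            lines.append(aid + "\t" + "\t".join(f"{row[n]:.6f}" for n in names))
        lines.append(
            "MEAN\t" + "\t".join(f"{self.mean(n):.6f}" for n in names)
        )
        lines.append("STD\t" + "\t".join(f"{self.std(n):.6f}" for n in names))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def evaluate(
    predictions: Mapping[str, Sequence[int]],
    gold: Mapping[str, GoldRanking | Sequence[int]],
    per_figure_count: bool = False,
    weights: WeightScheme = DEFAULT_WEIGHTS,
) -> MetricReport:
    """Evaluate predicted system ranks against gold rankings per article."""
    if set(predictions) != set(gold):
        missing = set(predictions) ^ set(gold)
        raise ValueError(f"article sets differ between predictions and gold: {missing}")
    per_article = {}
    for aid in predictions:
        ref = gold[aid]
        ref_ranks = ref.ranks if isinstance(ref, GoldRanking) else ref
        sys_ranks = predictions[aid]
        per_article[aid] = {
            "wer_rk": sim_wer_rk(sys_ranks, ref_ranks, weights),
            "ndcg": ndcg(sys_ranks, ref_ranks),
            "wer_fr": sim_wer_fr(sys_ranks, ref_ranks),
        }
    report = MetricReport(per_article)
    if per_figure_count:
        groups: dict[int, list[dict]] = {}
        for aid, row in per_article.items():
            ref = gold[aid]
            m = len(ref.ranks if isinstance(ref, GoldRanking) else ref)
            groups.setdefault(m, []).append(row)
        report.by_figure_count = {
            m: {name: float(np.mean([r[name] for r in rows])) for name in _METRICS}
            for m, rows in sorted(groups.items())
        }
    return report


def paired_one_tailed_ttest(
    better: Sequence[float], worse: Sequence[float]
) -> float:
    """p-value that `better` exceeds `worse` (paired, one tail)."""
    res = stats.ttest_rel(better, worse, alternative="greater")
    return float(res.pvalue)
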