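"""Ranking metrics, bootstrap intervals, baselines, and ranker comparison.

Rankers are scored against held-out referral episodes on three axes:

* precision@k and recall@k of the top-k recommended orders against the
  orders the specialist actually placed (k defaults to 4, the average
  first-visit workup size).  The precision denominator is fixed at k even
  when a ranker produces fewer candidates;
* ROC AUC, pooled over every (episode, candidate order) pair with the full
  trained target vocabulary as the candidate set and score 0 for anything a
  ranker leaves unscored (per-episode averaging is available behind a flag);
* 95% percentile bootstrap intervals over episode resamples (1000 draws by
  default), and a paired-bootstrap comparison of two rankers with a
  two-sided tail p-value.

Episodes with no target orders cannot be scored for recall and are excluded
from all metrics (counts are logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .association import AssociationMatrix, BackgroundStats
from .cohort import ReferralEpisode
from .ehr_model import ClinicalItem
from .errors import ColdStartError, ConfigurationError, UndefinedMetricError
from .recommender import WeightingScheme, _ranked_order, _score_vector

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Point estimates with CIs for one ranker on one episode set."""

    ranker: str
    k: int
    precision_at_k: float
    precision_ci: tuple[float, float]
    recall_at_k: float
    recall_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    n_episodes: int
    n_bootstrap: int
    seed: int | None

    def as_dict(self) -> dict:
        return {
            "ranker": self.ranker,
            "k": self.k,
            "precision_at_k": self.precision_at_k,
            "precision_ci": list(self.precision_ci),
            "recall_at_k": self.recall_at_k,
            "recall_ci": list(self.recall_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "n_episodes": self.n_episodes,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


def precision_recall_at_k(
    recommended: Sequence[ClinicalItem], actual: set[ClinicalItem], k: int = 4
) -> tuple[float, float]:
    """Precision and recall of the top-k recommendations.

    Precision divides by k regardless of list length (a short list is
    conceptually padded with misses); recall divides by ``|actual|``.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if not actual:
        raise UndefinedMetricError("recall undefined for an empty actual set")
    hits = len(set(recommended[:k]) & actual)
    return hits / k, hits / len(actual)


def roc_auc(
    scored_candidates: Sequence[Mapping[ClinicalItem, float]],
    actuals: Sequence[set[ClinicalItem]],
    candidates: Sequence[ClinicalItem],
    per_episode: bool = False,
) -> float:
    """Midrank-tie ROC AUC over pooled (episode, candidate) pairs.

    Labels are membership of the candidate in the episode's actual order set;
    unscored candidates contribute score 0.  ``per_episode=True`` averages
    per-episode AUCs (episodes with a single class are skipped) instead of
    pooling.
    """
    if len(scored_candidates) != len(actuals):
        raise ConfigurationError("scores and actuals must align")
    label_blocks, score_blocks = [], []
    for scores, actual in zip(scored_candidates, actuals):
        label_blocks.append(np.array([b in actual for b in candidates], dtype=bool))
        score_blocks.append(np.array([scores.get(b, 0.0) for b in candidates], dtype=float))
    if per_episode:
        aucs = [
            roc_auc_score(lab, sc)
            for lab, sc in zip(label_blocks, score_blocks)
            if 0 < lab.sum() < len(lab)
        ]
        if not aucs:
            raise UndefinedMetricError("no episode has both classes")
        return float(np.mean(aucs))
    labels = np.concatenate(label_blocks)
    scores = np.concatenate(score_blocks)
    if labels.all() or not labels.any():
        raise UndefinedMetricError("AUC undefined: all labels identical")
    return float(roc_auc_score(labels, scores))


def bootstrap_ci(
    metric_fn: Callable[[Sequence], float],
    episodes: Sequence,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for ``metric_fn`` over episode resamples.

    Episodes (i.e. patients) are resampled with replacement.  A resample on
    which the metric is undefined is redrawn up to 10 times before erroring.
    Deterministic given the seed.
    """
    if not episodes:
        raise ConfigurationError("episodes must be non-empty")
    rng = np.random.default_rng(seed)
    point = metric_fn(episodes)
    n = len(episodes)
    stats = np.empty(n_resamples)
    for r in range(n_resamples):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                stats[r] = metric_fn([episodes[int(i)] for i in idx])
                break
            except UndefinedMetricError:
                logger.debug("bootstrap resample %d undefined (attempt %d), redrawing", r, attempt)
        else:
            raise UndefinedMetricError("metric undefined on 10 consecutive resamples")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(point), float(lower), float(upper)


# -- rankers -----------------------------------------------------------------


class RecommenderRanker:
    """The trained association recommender behind the common ranker interface."""

    name = "recommender"

    def __init__(
        self,
        matrix: AssociationMatrix,
        background: BackgroundStats | None,
        scheme: WeightingScheme = WeightingScheme(),
    ):
        self.matrix = matrix
        self.background = background
        self.scheme = scheme

    def score_targets(self, episode: ReferralEpisode) -> np.ndarray:
        """Scores aligned with ``matrix.targets``; cold start → prevalence."""
        try:
            _, scores, _ = _score_vector(
                episode.query_items, self.matrix, self.background, self.scheme
            )
            return np.asarray(scores, dtype=float)
        except ColdStartError:
            return self.matrix.target_prevalence_array().astype(float)

    def ranked_items(self, episode: ReferralEpisode) -> list[ClinicalItem]:
        scores = self.score_targets(episode)
        return [self.matrix.targets[i] for i in _ranked_order(self.matrix, scores)]


class _PrevalenceRanker:
    """Query-independent ranking by a fixed per-candidate prevalence."""

    def __init__(self, name: str, matrix: AssociationMatrix, scores: np.ndarray):
        self.name = name
        self.matrix = matrix
        self._scores = np.asarray(scores, dtype=float)

    def score_targets(self, episode: ReferralEpisode) -> np.ndarray:
        return self._scores

    def ranked_items(self, episode: ReferralEpisode) -> list[ClinicalItem]:
        return [self.matrix.targets[i] for i in _ranked_order(self.matrix, self._scores)]


class _RandomRanker:
    """Per-episode random permutation of the candidate orders.

    Reproducible for a fixed seed and a fixed sequence of score requests
    (one draw per call, consumed in episode order).
    """

    name = "random"

    def __init__(self, matrix: AssociationMatrix, seed: int | None):
        self.matrix = matrix
        self._rng = np.random.default_rng(seed)

    def score_targets(self, episode: ReferralEpisode) -> np.ndarray:
        return self._rng.random(len(self.matrix.targets))

    def ranked_items(self, episode: ReferralEpisode) -> list[ClinicalItem]:
        scores = self.score_targets(episode)
        return [self.matrix.targets[i] for i in _ranked_order(self.matrix, scores)]


def baseline_ranker(
    kind: str,
    matrix: AssociationMatrix,
    background: BackgroundStats | None = None,
    seed: int | None = None,
):
    """Reference rankers: ``endocrine_prevalence`` (cohort best-sellers),
    ``outpatient_prevalence``, or ``random``."""
    if kind == "endocrine_prevalence":
        return _PrevalenceRanker(kind, matrix, matrix.target_prevalence_array())
    if kind == "outpatient_prevalence":
        if background is None:
            raise ConfigurationError("outpatient_prevalence baseline needs background stats")
        scores = np.array([background.prevalence(b) for b in matrix.targets])
        return _PrevalenceRanker(kind, matrix, scores)
    if kind == "random":
        return _RandomRanker(matrix, seed)
    raise ConfigurationError(f"unknown baseline kind {kind!r}")


# -- evaluation driver -------------------------------------------------------


@dataclass
class _EpisodeScores:
    """Precomputed per-episode arrays so bootstrap resampling is cheap."""

    precision: float
    recall: float
    labels: np.ndarray
    scores: np.ndarray


def _score_episodes(ranker, matrix, episodes, k) -> list[_EpisodeScores]:
    out = []
    for ep in episodes:
        scores = ranker.score_targets(ep)
        top = _ranked_order(matrix, scores)[:k]
        hits = sum(1 for i in top if matrix.targets[i] in ep.target_items)
        labels = np.array([b in ep.target_items for b in matrix.targets], dtype=bool)
        out.append(
            _EpisodeScores(
                precision=hits / k,
                recall=hits / len(ep.target_items),
                labels=labels,
                scores=np.asarray(scores, dtype=float),
            )
        )
    return out


def _pooled_auc(cells: Sequence[_EpisodeScores]) -> float:
    labels = np.concatenate([c.labels for c in cells])
    scores = np.concatenate([c.scores for c in cells])
    if labels.all() or not labels.any():
        raise UndefinedMetricError("AUC undefined: all labels identical")
    return float(roc_auc_score(labels, scores))


def evaluate_rankers(
    rankers: Mapping[str, object],
    matrix: AssociationMatrix,
    episodes: Sequence[ReferralEpisode],
    k: int = 4,
    n_bootstrap: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> dict[str, EvalResult]:
    """Score several rankers on one episode set (the benchmark-table driver).

    Episodes without target orders are excluded up front.  Each ranker's
    random stream is pre-consumed in episode order once, so bootstrap
    resampling reuses identical per-episode scores.
    """
    scorable = [ep for ep in episodes if ep.target_items]
    dropped = len(episodes) - len(scorable)
    if dropped:
        logger.info("evaluate_rankers: excluded %d episodes with no target orders", dropped)
    if not scorable:
        raise UndefinedMetricError("no scorable episodes")
    results = {}
    for i, (name, ranker) in enumerate(rankers.items()):
        cells = _score_episodes(ranker, matrix, scorable, k)
        boot_seed = None if seed is None else seed + 1000 * i
        p_point, p_lo, p_hi = bootstrap_ci(
            lambda cs: float(np.mean([c.precision for c in cs])),
            cells, n_resamples=n_bootstrap, level=level, seed=boot_seed,
        )
        r_point, r_lo, r_hi = bootstrap_ci(
            lambda cs: float(np.mean([c.recall for c in cs])),
            cells, n_resamples=n_bootstrap, level=level,
            seed=None if boot_seed is None else boot_seed + 1,
        )
        a_point, a_lo, a_hi = bootstrap_ci(
            _pooled_auc, cells, n_resamples=n_bootstrap, level=level,
            seed=None if boot_seed is None else boot_seed + 2,
        )
        results[name] = EvalResult(
            ranker=name, k=k,
            precision_at_k=p_point, precision_ci=(p_lo, p_hi),
            recall_at_k=r_point, recall_ci=(r_lo, r_hi),
            auc=a_point, auc_ci=(a_lo, a_hi),
            n_episodes=len(scorable), n_bootstrap=n_bootstrap, seed=seed,
        )
    return results


def compare_rankers(
    ranker1,
    ranker2,
    matrix: AssociationMatrix,
    episodes: Sequence[ReferralEpisode],
    metric: str = "precision",
    k: int = 4,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float], float]:
    """Paired bootstrap of the per-episode metric difference (r1 − r2).

    Returns the point delta, its percentile CI, and a two-sided p-value from
    the bootstrap distribution's tail fraction.
    """
    if metric not in ("precision", "recall"):
        raise ConfigurationError(f"unknown comparison metric {metric!r}")
    scorable = [ep for ep in episodes if ep.target_items]
    if not scorable:
        raise UndefinedMetricError("no scorable episodes")
    cells1 = _score_episodes(ranker1, matrix, scorable, k)
    cells2 = _score_episodes(ranker2, matrix, scorable, k)
    v1 = np.array([getattr(c, metric) for c in cells1])
    v2 = np.array([getattr(c, metric) for c in cells2])
    diffs = v1 - v2
    delta = float(diffs.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diffs), size=(n_resamples, len(diffs)))
    boot = diffs[idx].mean(axis=1)
    lo, hi = np.quantile(boot, [0.025, 0.975])
    p = 2.0 * min(float(np.mean(boot <= 0.0)), float(np.mean(boot >= 0.0)))
    return delta, (float(lo), float(hi)), min(p, 1.0)
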