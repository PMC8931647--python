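"""Query weighting, score aggregation, ranking, and weighting-scheme selection.

A patient's chart at referral time usually carries several query items
A_1..A_q.  Each item induces its own PPV-ranked list of candidate orders;
these are aggregated into one score per candidate order B as a weighted
pseudo-count sum

    score(B) = sum_i  W_{A_i} * PPV(A_i, B)

over the query items present in the trained vocabulary.  The weight W_A
encodes how informative a chart item is:

``uniform``            W_A = 1
``inverse_frequency``  W_A = 1 / ln(1 + N_A)   (or 1/N_A behind a switch)
``relative_risk``      W_A = RR_A, the cohort-enrichment of A
``combined``           W_A = RR_A / ln(1 + N_A)

Common primary-care items (well-child checks, URIs, routine vaccines) are
frequent both inside and outside the referral cohort; the inverse-frequency
term penalizes ubiquity and the relative-risk term penalizes irrelevance to
the specialty, and their combination typically wins cross-validation.
Normalizing by the weight sum is omitted from the ranking score since it is
rank-invariant for a fixed query.

Queries with no item in the trained vocabulary are a cold start and fall back
to the cohort-prevalence "best seller" ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .association import (
    AssociationMatrix,
    BackgroundStats,
    build_matrix,
    ppv,
    relative_ratio,
    relative_risk_weight,
)
from .cohort import ReferralEpisode
from .errors import ColdStartError, ConfigurationError, UntrainedModelError

logger = logging.getLogger(__name__)

SCHEME_NAMES = ("uniform", "inverse_frequency", "relative_risk", "combined")


@dataclass(frozen=True)
class WeightingScheme:
    """Named query-item weighting strategy with its parameters.

    ``scale`` multiplies every weight; rankings are invariant to it and it
    exists to make that property testable/configurable.  ``inverse_form``
    chooses between the bounded ``1/ln(1+N_A)`` penalty (default) and a raw
    ``1/N_A`` alternative.
    """

    name: str = "combined"
    max_rr_cap: float = 100.0
    inverse_form: str = "log"  # "log" -> 1/ln(1+N), "linear" -> 1/N
    scale: float = 1.0

    def __post_init__(self):
        if self.name not in SCHEME_NAMES:
            raise ConfigurationError(f"unknown weighting scheme {self.name!r}")
        if self.inverse_form not in ("log", "linear"):
            raise ConfigurationError(f"unknown inverse form {self.inverse_form!r}")
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")


@dataclass
class RecommendationEntry:
    """One ranked candidate order with its interpretability statistics."""

    item: "ClinicalItem"
    score: float
    ppv: float
    relative_ratio: float
    endocrine_prevalence: float
    outpatient_prevalence: float


@dataclass
class RecommendationList:
    episode_id: str
    entries: list[RecommendationEntry]
    scheme: str
    fallback_used: bool


def item_weight(
    scheme: WeightingScheme,
    matrix: AssociationMatrix,
    background: BackgroundStats | None,
    a: "ClinicalItem",
) -> float:
    """Weight W_A of one query item under the scheme; unknown items weigh 0."""
    n_a = matrix.query_counts.get(a, 0)
    if n_a == 0:
        return 0.0
    if scheme.name == "uniform":
        w = 1.0
    elif scheme.name == "inverse_frequency":
        w = _inverse_penalty(scheme, n_a)
    elif scheme.name == "relative_risk":
        w = _rr(scheme, matrix, background, a)
    else:  # combined
        w = _rr(scheme, matrix, background, a) * _inverse_penalty(scheme, n_a)
    return scheme.scale * w


def _inverse_penalty(scheme: WeightingScheme, n_a: int) -> float:
    if scheme.inverse_form == "linear":
        return 1.0 / n_a
    return 1.0 / math.log(1.0 + n_a)


def _rr(scheme, matrix, background, a) -> float:
    if background is None:
        raise ConfigurationError(
            f"scheme {scheme.name!r} requires outpatient background statistics"
        )
    return relative_risk_weight(matrix, background, a, max_weight=scheme.max_rr_cap)


def _effective_query(
    query_items: Iterable["ClinicalItem"], matrix: AssociationMatrix
) -> list["ClinicalItem"]:
    return sorted(a for a in query_items if matrix.query_counts.get(a, 0) > 0)


def aggregate_scores(
    query_items: Iterable["ClinicalItem"],
    matrix: AssociationMatrix,
    background: BackgroundStats | None,
    scheme: WeightingScheme,
) -> dict["ClinicalItem", float]:
    """Weighted pseudo-count score for every candidate target order.

    Raises :class:`ColdStartError` when no query item is in the trained
    vocabulary; callers fall back to prevalence ranking.
    """
    targets, scores, _ = _score_vector(query_items, matrix, background, scheme)
    return dict(zip(targets, scores))


def _score_vector(query_items, matrix, background, scheme):
    """(targets, score vector, weight sum); vectorized over the PPV array."""
    effective = _effective_query(query_items, matrix)
    if not effective:
        raise ColdStartError("no query item present in the trained vocabulary")
    qindex = matrix.query_index
    rows = np.array([qindex[a] for a in effective])
    weights = np.array([item_weight(scheme, matrix, background, a) for a in effective])
    scores = weights @ matrix.ppv_array()[rows]
    return matrix.targets, scores, float(weights.sum())


def _ranked_order(matrix: AssociationMatrix, scores: np.ndarray) -> list[int]:
    """Indices sorted by score desc, then cohort prevalence desc, then item key."""
    prev = matrix.target_prevalence_array()
    items = matrix.targets
    return sorted(
        range(len(items)), key=lambda i: (-scores[i], -prev[i], items[i].key)
    )


def recommend(
    episode: ReferralEpisode | Iterable["ClinicalItem"],
    matrix: AssociationMatrix,
    background: BackgroundStats | None,
    scheme: WeightingScheme = WeightingScheme(),
    k: int = 4,
    episode_id: str = "",
) -> RecommendationList:
    """Top-``k`` recommended workup orders for one referral query.

    The per-entry ``ppv`` is the weight-normalized aggregate score (equal to
    the single-item PPV when the effective query has one item) and
    ``relative_ratio`` is the maximum over effective query items.  Cold-start
    queries are ranked by cohort prevalence with ``fallback_used`` set.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if matrix.n_cohort == 0 or not matrix.target_counts:
        raise UntrainedModelError("association matrix has no trained targets")
    if isinstance(episode, ReferralEpisode):
        query_items = episode.query_items
        episode_id = episode_id or episode.patient_id
    else:
        query_items = frozenset(episode)

    fallback = False
    try:
        targets, scores, weight_sum = _score_vector(query_items, matrix, background, scheme)
        effective = _effective_query(query_items, matrix)
    except ColdStartError:
        fallback = True
        targets = matrix.targets
        scores = matrix.target_prevalence_array()
        weight_sum = 0.0
        effective = []

    order = _ranked_order(matrix, scores)[:k]
    prev = matrix.target_prevalence_array()
    entries = []
    for i in order:
        b = targets[i]
        if fallback:
            agg_ppv = prev[i]
            rr_b = math.nan
        else:
            agg_ppv = scores[i] / weight_sum if weight_sum > 0 else 0.0
            ratios = [
                relative_ratio(matrix, a, b)
                for a in effective
                if 0 < matrix.query_counts[a] < matrix.n_cohort
            ]
            finite_or_inf = [r for r in ratios if not math.isnan(r)]
            rr_b = max(finite_or_inf) if finite_or_inf else math.nan
        entries.append(
            RecommendationEntry(
                item=b,
                score=float(scores[i]),
                ppv=float(agg_ppv),
                relative_ratio=rr_b,
                endocrine_prevalence=float(prev[i]),
                outpatient_prevalence=background.prevalence(b) if background else math.nan,
            )
        )
    return RecommendationList(
        episode_id=episode_id, entries=entries, scheme=scheme.name, fallback_used=fallback
    )


def _precision_at_k(matrix, scores, actual, k) -> float:
    top = _ranked_order(matrix, scores)[:k]
    hits = sum(1 for i in top if matrix.targets[i] in actual)
    return hits / k


def select_weighting(
    train_episodes: Sequence[ReferralEpisode],
    background: BackgroundStats | None,
    schemes: Sequence[WeightingScheme] | None = None,
    n_folds: int = 10,
    k: int = 4,
    seed: int = 0,
) -> tuple[WeightingScheme, dict[str, dict]]:
    """Choose the weighting scheme by patient-level K-fold cross-validation.

    Episodes (one per patient) are shuffled with the seed and split into
    ``n_folds`` folds; for each fold the matrix is rebuilt on the remaining
    folds and mean precision@k is measured on the held-out fold.  The scheme
    with the best mean-of-folds precision wins; ties go to the first scheme
    in the candidate order.  Returns the winner and the per-scheme CV table.
    """
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if len(train_episodes) < n_folds:
        raise ConfigurationError(
            f"{len(train_episodes)} episodes cannot fill {n_folds} folds"
        )
    if schemes is None:
        schemes = [WeightingScheme(name=n) for n in SCHEME_NAMES]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_episodes))
    folds = np.array_split(order, n_folds)

    fold_means: dict[str, list[float]] = {s.name: [] for s in schemes}
    for fold in folds:
        held = set(int(i) for i in fold)
        fit = [ep for i, ep in enumerate(train_episodes) if i not in held]
        val = [train_episodes[int(i)] for i in fold]
        fold_matrix = build_matrix(fit)
        for scheme in schemes:
            precisions = []
            for ep in val:
                if not ep.target_items:
                    continue
                try:
                    _, scores, _ = _score_vector(ep.query_items, fold_matrix, background, scheme)
                except ColdStartError:
                    scores = fold_matrix.target_prevalence_array()
                precisions.append(_precision_at_k(fold_matrix, scores, ep.target_items, k))
            fold_means[scheme.name].append(float(np.mean(precisions)) if precisions else 0.0)

    table = {
        s.name: {
            "mean_precision_at_k": float(np.mean(fold_means[s.name])),
            "fold_precisions": fold_means[s.name],
        }
        for s in schemes
    }
    best = max(schemes, key=lambda s: table[s.name]["mean_precision_at_k"])
    # max() keeps the first maximal scheme, i.e. candidate-order tie-breaking
    logger.info(
        "select_weighting: %s wins with mean precision@%d %.4f",
        best.name, k, table[best.name]["mean_precision_at_k"],
    )
    return best, table
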