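"""Item co-occurrence association matrix and its derived statistics.

Training counts, over the referral cohort's episodes, how many distinct
patients carry query item A on their chart before referral (N_A), how many
received target order B at the first specialty visit, and how many did both
(N_AB).  Pairs are directional — chart item at referral time → specialist
order — because the quantity of interest is the posttest probability
P(B|A) = N_AB / N_A, the positive predictive value of A for B.

Alongside PPV the matrix exposes:

* the relative ratio P(B|A) / P(B|not A), an interestingness measure that
  flags orders specific to a finding rather than merely popular;
* the relative-risk query weight RR_A = (N_A / N_cohort) /
  (N_A^out / N_out), the enrichment of item A in the referral cohort
  relative to outpatients outside the cohort, used to downweight
  specialty-irrelevant chart items;
* cohort and outpatient prevalences of any item.

Counts are per-patient (duplicates within a patient count once), and the
matrix is persisted sparsely as triplet rows; a dense table over the full
vocabulary cross-product would be prohibitive at realistic vocabulary sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ReferralEpisode
from .ehr_model import ClinicalItem
from .errors import SchemaError, UndefinedQueryError

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Sparse directional co-occurrence counts for one training cohort."""

    n_cohort: int
    query_counts: dict[ClinicalItem, int]
    target_counts: dict[ClinicalItem, int]
    pair_counts: dict[tuple[ClinicalItem, ClinicalItem], int]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        for (a, b), n_ab in self.pair_counts.items():
            n_a = self.query_counts.get(a, 0)
            n_b = self.target_counts.get(b, 0)
            if not (0 <= n_ab <= min(n_a, n_b) <= self.n_cohort):
                raise ValueError(
                    f"inconsistent counts for pair ({a!r}, {b!r}): "
                    f"n_ab={n_ab}, n_a={n_a}, n_b={n_b}, n_cohort={self.n_cohort}"
                )

    # -- dense views (built lazily; ordering is deterministic) ---------------

    @property
    def queries(self) -> list[ClinicalItem]:
        if "queries" not in self._cache:
            self._cache["queries"] = sorted(self.query_counts)
        return self._cache["queries"]

    @property
    def targets(self) -> list[ClinicalItem]:
        if "targets" not in self._cache:
            self._cache["targets"] = sorted(self.target_counts)
        return self._cache["targets"]

    @property
    def query_index(self) -> dict[ClinicalItem, int]:
        if "qindex" not in self._cache:
            self._cache["qindex"] = {it: i for i, it in enumerate(self.queries)}
        return self._cache["qindex"]

    @property
    def target_index(self) -> dict[ClinicalItem, int]:
        if "tindex" not in self._cache:
            self._cache["tindex"] = {it: i for i, it in enumerate(self.targets)}
        return self._cache["tindex"]

    def ppv_array(self) -> np.ndarray:
        """Dense PPV lookup, shape (n query items, n target items)."""
        if "ppv" not in self._cache:
            arr = np.zeros((len(self.queries), len(self.targets)))
            qi, ti = self.query_index, self.target_index
            for (a, b), n_ab in self.pair_counts.items():
                arr[qi[a], ti[b]] = n_ab / self.query_counts[a]
            self._cache["ppv"] = arr
        return self._cache["ppv"]

    def target_prevalence_array(self) -> np.ndarray:
        if "tprev" not in self._cache:
            self._cache["tprev"] = np.array(
                [self.target_counts[b] / self.n_cohort for b in self.targets]
            )
        return self._cache["tprev"]


def build_matrix(train_episodes: Sequence[ReferralEpisode]) -> AssociationMatrix:
    """Count query-item / target-order co-occurrences over training episodes.

    Episodes are assumed pre-filtered by the vocabulary.  Because query and
    target sides of an episode are sets, all counts are automatically
    per-patient.
    """
    if not train_episodes:
        raise ValueError("train_episodes must be non-empty")
    query_counts: dict[ClinicalItem, int] = {}
    target_counts: dict[ClinicalItem, int] = {}
    pair_counts: dict[tuple[ClinicalItem, ClinicalItem], int] = {}
    for ep in train_episodes:
        for a in ep.query_items:
            query_counts[a] = query_counts.get(a, 0) + 1
        for b in ep.target_items:
            target_counts[b] = target_counts.get(b, 0) + 1
        for a in ep.query_items:
            for b in ep.target_items:
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    return AssociationMatrix(
        n_cohort=len(train_episodes),
        query_counts=query_counts,
        target_counts=target_counts,
        pair_counts=pair_counts,
    )


@dataclass
class BackgroundStats:
    """Outpatient-wide per-item patient counts (the RR_A denominator source)."""

    n_outpt: int
    outpt_counts: dict[ClinicalItem, int]

    def __post_init__(self):
        bad = [it for it, n in self.outpt_counts.items() if n > self.n_outpt or n < 0]
        if bad:
            raise ValueError(f"outpatient count exceeds population for {bad[:3]}")

    def prevalence(self, item: ClinicalItem) -> float:
        if item not in self.outpt_counts:
            logger.warning("unknown item %r in background prevalence, returning 0", item)
            return 0.0
        return self.outpt_counts[item] / self.n_outpt


def ppv(matrix: AssociationMatrix, a: ClinicalItem, b: ClinicalItem) -> float:
    """Posttest probability P(B|A) = N_AB / N_A, unsmoothed."""
    n_a = matrix.query_counts.get(a, 0)
    if n_a == 0:
        raise UndefinedQueryError(f"query item {a!r} has N_A = 0")
    return matrix.pair_counts.get((a, b), 0) / n_a


def relative_risk_weight(
    matrix: AssociationMatrix,
    background: BackgroundStats,
    a: ClinicalItem,
    max_weight: float = 100.0,
) -> float:
    """Cohort enrichment RR_A of query item A.

    Numerator: prevalence of A in the referral cohort.  Denominator:
    prevalence of A among outpatients *outside* the cohort, obtained by
    subtracting the cohort's contribution from the outpatient-wide counts.
    A zero denominator yields the configured cap; finite ratios are clipped
    at the same cap so aggregation weights stay bounded.
    """
    n_a = matrix.query_counts.get(a, 0)
    cohort_prev = n_a / matrix.n_cohort
    n_out_excl = max(background.outpt_counts.get(a, 0) - n_a, 0)
    pop_out_excl = background.n_outpt - matrix.n_cohort
    if cohort_prev == 0.0:
        return 0.0
    if pop_out_excl <= 0 or n_out_excl == 0:
        return max_weight
    return min(cohort_prev / (n_out_excl / pop_out_excl), max_weight)


def relative_ratio(matrix: AssociationMatrix, a: ClinicalItem, b: ClinicalItem) -> float:
    """Interestingness ratio P(B|A) / P(B|not A).

    Returns ``inf`` when B never occurs without A but does with it, and
    ``nan`` when B occurs in neither stratum (both probabilities zero).
    """
    n_a = matrix.query_counts.get(a, 0)
    if not 0 < n_a < matrix.n_cohort:
        raise UndefinedQueryError(
            f"relative ratio undefined for {a!r}: N_A={n_a} of {matrix.n_cohort}"
        )
    n_ab = matrix.pair_counts.get((a, b), 0)
    p_given_a = n_ab / n_a
    p_given_not_a = (matrix.target_counts.get(b, 0) - n_ab) / (matrix.n_cohort - n_a)
    if p_given_not_a == 0.0:
        return math.inf if p_given_a > 0 else math.nan
    return p_given_a / p_given_not_a


def prevalence(source: AssociationMatrix | BackgroundStats, item: ClinicalItem) -> float:
    """Fraction of the source population carrying ``item``.

    On an association matrix, target-order counts take precedence (the
    Table-style "cohort prevalence" of an order); chart items not among the
    targets fall back to query-side counts.  Unknown items are 0 with a
    warning.
    """
    if isinstance(source, BackgroundStats):
        return source.prevalence(item)
    if item in source.target_counts:
        return source.target_counts[item] / source.n_cohort
    if item in source.query_counts:
        return source.query_counts[item] / source.n_cohort
    logger.warning("unknown item %r in cohort prevalence, returning 0", item)
    return 0.0


# -- persistence -------------------------------------------------------------

_MATRIX_COLUMNS = (
    "query_concept", "query_qualifier", "query_domain",
    "target_concept", "target_domain",
    "n_a", "n_b", "n_ab", "n_cohort",
)


def write_matrix(matrix: AssociationMatrix, path: str | Path) -> None:
    """Persist as sparse triplets plus marginal-only rows.

    Pair rows carry both items; marginal rows (one side blank) preserve query
    items with no observed pairs and target counts, so a round trip is exact.
    """
    rows = []
    for (a, b), n_ab in sorted(matrix.pair_counts.items()):
        rows.append(
            (a.concept_id, a.qualifier, a.domain, b.concept_id, b.domain,
             matrix.query_counts[a], matrix.target_counts[b], n_ab, matrix.n_cohort)
        )
    paired_queries = {a for a, _ in matrix.pair_counts}
    paired_targets = {b for _, b in matrix.pair_counts}
    for a in sorted(set(matrix.query_counts) - paired_queries):
        rows.append((a.concept_id, a.qualifier, a.domain, "", "",
                     matrix.query_counts[a], "", "", matrix.n_cohort))
    for b in sorted(set(matrix.target_counts) - paired_targets):
        rows.append(("", "", "", b.concept_id, b.domain,
                     "", matrix.target_counts[b], "", matrix.n_cohort))
    pd.DataFrame(rows, columns=list(_MATRIX_COLUMNS)).to_csv(path, index=False)


def read_matrix(path: str | Path) -> AssociationMatrix:
    df = pd.read_csv(path, dtype={c: "string" for c in _MATRIX_COLUMNS[:5]})
    for col in _MATRIX_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    n_cohort = int(df["n_cohort"].astype(float).max())
    query_counts: dict[ClinicalItem, int] = {}
    target_counts: dict[ClinicalItem, int] = {}
    pair_counts: dict[tuple[ClinicalItem, ClinicalItem], int] = {}
    for row in df.itertuples(index=False):
        a = b = None
        if pd.notna(row.query_concept) and row.query_concept != "":
            a = ClinicalItem(str(row.query_concept), str(row.query_domain), str(row.query_qualifier))
            query_counts[a] = int(float(row.n_a))
        if pd.notna(row.target_concept) and row.target_concept != "":
            b = ClinicalItem(str(row.target_concept), str(row.target_domain))
            target_counts[b] = int(float(row.n_b))
        if a is not None and b is not None:
            pair_counts[(a, b)] = int(float(row.n_ab))
    return AssociationMatrix(
        n_cohort=n_cohort,
        query_counts=query_counts,
        target_counts=target_counts,
        pair_counts=pair_counts,
    )


def write_background(background: BackgroundStats, path: str | Path) -> None:
    rows = [
        (it.concept_id, it.qualifier, it.domain, n, background.n_outpt)
        for it, n in sorted(background.outpt_counts.items())
    ]
    pd.DataFrame(
        rows, columns=["concept", "qualifier", "domain", "n_outpt_item", "n_outpt"]
    ).to_csv(path, index=False)


def read_background(path: str | Path) -> BackgroundStats:
    df = pd.read_csv(path, dtype={"concept": "string", "qualifier": "string", "domain": "string"})
    for col in ("concept", "qualifier", "n_outpt_item", "n_outpt"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    counts = {}
    for row in df.itertuples(index=False):
        domain = str(row.domain) if "domain" in df.columns and pd.notna(row.domain) else "condition"
        item = ClinicalItem(str(row.concept), domain, str(row.qualifier))
        counts[item] = int(row.n_outpt_item)
    n_outpt = int(df["n_outpt"].max()) if len(df) else 0
    return BackgroundStats(n_outpt=n_outpt, outpt_counts=counts)
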