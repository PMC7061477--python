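"""Individual cause assignment by ranking against a resampled baseline.

A record's tariff score for a cause is meaningless on its own; what matters
is where that score *ranks* among scores of a reference population.  The
reference is a uniform-by-cause resample of the gold-standard database
(equal numbers of each cause, drawn with replacement) scored by the same
tariff matrix, so the baseline's cause composition carries no information
about the population CSMF.

For each candidate cause, a record's rank is 1 + the number of baseline
scores strictly greater than its own (rank 1 is best; ties favour the
record).  The cause with the lowest rank wins unless one of the cutoff
rules fires, in which case the record is assigned the reserved
``undetermined`` category:

(a) the winning rank exceeds ``rank_quantile_cutoff`` x baseline size,
(b) the winning score is below ``minimum_score``, or
(c) the winning rank exceeds ``overall_rank_cap`` x baseline size.

Demographic restrictions (e.g. maternal causes only for women of
reproductive age) remove causes from contention before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .schema import (
    DEFAULT_AGE_SCHEME,
    UNDETERMINED,
    AgeGroupScheme,
    CauseList,
    SymptomSchema,
    VARecord,
    bin_age,
)
from .tariff import TariffMatrix, compute_endorsement_rates, compute_tariffs, endorsement_array, score_matrix


@dataclass(frozen=True)
class CutoffPolicy:
    """Thresholds governing when a record is left undetermined.

    Defaults mirror the public adult configuration of the deployed tariff
    software: a rank-quantile cutoff of 0.89, no minimum score, and no
    separate overall rank cap.  All three are configuration, not code.
    """

    rank_quantile_cutoff: float = 0.89
    minimum_score: float = 0.0
    overall_rank_cap: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.rank_quantile_cutoff <= 1):
            raise ValueError("rank_quantile_cutoff must lie in (0, 1]")
        if np.isnan(self.minimum_score) or self.minimum_score == np.inf:
            raise ValueError("minimum_score must be a number or -inf (disabled)")
        if not (0 < self.overall_rank_cap <= 1):
            raise ValueError("overall_rank_cap must lie in (0, 1]")


#: A policy under which no record is ever left undetermined by rule (a)/(c)
#: and rule (b) only fires for -inf scores; useful for accuracy studies.
NO_CUTOFFS = CutoffPolicy(rank_quantile_cutoff=1.0, minimum_score=-np.inf, overall_rank_cap=1.0)


@dataclass(frozen=True)
class Restriction:
    """Demographic eligibility for one cause."""

    sexes: tuple[str, ...] = ("male", "female")
    age_min: float = 0.0
    age_max: float = float("inf")

    def allows(self, sex: str, age_years: float | None) -> bool:
        # Unknown demographics never exclude a cause: the restriction is a
        # filter on positively contradicting evidence only.
        if sex != "unknown" and sex not in self.sexes:
            return False
        if age_years is not None and not (self.age_min <= age_years <= self.age_max):
            return False
        return True


@dataclass(frozen=True)
class CauseRestrictions:
    """Editable table of per-cause demographic restrictions (data, not code)."""

    rules: Mapping[str, Restriction] = field(default_factory=dict)

    def eligible(self, cause_id: str, sex: str, age_years: float | None) -> bool:
        rule = self.rules.get(cause_id)
        return True if rule is None else rule.allows(sex, age_years)

    def eligibility_vector(
        self, causes: Sequence[str], sex: str, age_years: float | None
    ) -> np.ndarray:
        return np.array([self.eligible(c, sex, age_years) for c in causes], dtype=bool)


NO_RESTRICTIONS = CauseRestrictions()


@dataclass(frozen=True)
class RankBaseline:
    """Sorted score lists per cause for a uniform-by-cause resample.

    ``scores[i]`` holds, in descending order, the scores of every resampled
    record under cause i's tariff row.  All causes share the same resample,
    so the lists have equal length ``size``.
    """

    causes: tuple[str, ...]
    scores: np.ndarray  # shape (n_causes, size), each row sorted descending
    per_cause_n: int
    seed: int

    @property
    def size(self) -> int:
        return self.scores.shape[1]

    def ascending(self) -> np.ndarray:
        # Views sorted ascending for searchsorted-based ranking.
        return self.scores[:, ::-1]


def build_rank_baseline(
    db: Sequence,
    tariffs: TariffMatrix,
    per_cause_n: int = 100,
    seed: int = 0,
) -> RankBaseline:
    """Resample the gold standard uniformly by cause and score the resample.

    With replacement, ``per_cause_n`` records of *each* cause are drawn, so
    the baseline's cause composition is uniform regardless of the training
    database's.  Reproducible given the seed.
    """
    if not len(db):
        raise ValueError("cannot build a rank baseline from an empty database")
    if per_cause_n < 1:
        raise ValueError("per_cause_n must be >= 1")
    rng = np.random.default_rng(seed)
    schema = SymptomSchema(tariffs.symptoms)
    y = endorsement_array(db, schema)
    labels = np.array([r.true_cause for r in db])
    chosen: list[np.ndarray] = []
    for cause in tariffs.causes:
        pool = np.flatnonzero(labels == cause)
        if pool.size == 0:
            raise ValueError(f"cause {cause!r} has no records in the database")
        chosen.append(rng.choice(pool, size=per_cause_n, replace=True))
    resample = np.concatenate(chosen)
    scores = score_matrix(y[resample], tariffs)  # (n_resample, n_causes)
    ordered = np.sort(scores.T, axis=1)[:, ::-1]
    return RankBaseline(tariffs.causes, ordered, per_cause_n, seed)


def rank_score(score: float, baseline_list: np.ndarray) -> int:
    """Rank of a score within a descending baseline list (1 = best).

    The rank counts baseline entries strictly greater than the score, so
    ties are broken in the record's favour.
    """
    baseline_list = np.asarray(baseline_list, dtype=float)
    if baseline_list.size == 0:
        raise ValueError("baseline list is empty")
    return 1 + int(np.sum(baseline_list > score))


def _rank_matrix(scores: np.ndarray, baseline: RankBaseline) -> np.ndarray:
    """Ranks (n_records x n_causes) of scores within each cause's baseline."""
    asc = baseline.ascending()
    ranks = np.empty(scores.shape, dtype=np.int64)
    for j in range(scores.shape[1]):
        greater = baseline.size - np.searchsorted(asc[j], scores[:, j], side="right")
        ranks[:, j] = 1 + greater
    return ranks


@dataclass(frozen=True)
class TopCause:
    cause_id: str
    score: float
    rank: int


@dataclass(frozen=True)
class IndividualPrediction:
    """Assigned cause (or undetermined) plus the ranked top-k candidates."""

    record_id: str
    assigned_cause: str
    top_k: tuple[TopCause, ...]
    age_group: str
    sex: str


def _candidate_order(
    scores_r: np.ndarray, ranks_r: np.ndarray, eligible: np.ndarray
) -> np.ndarray:
    """Eligible cause indices sorted by ascending rank, then descending
    score, then cause-list order."""
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return idx
    order = np.lexsort((idx, -scores_r[idx], ranks_r[idx]))
    return idx[order]


def assign_all(
    records: Sequence[VARecord],
    tariffs: TariffMatrix,
    baseline: RankBaseline,
    policy: CutoffPolicy = CutoffPolicy(),
    restrictions: CauseRestrictions = NO_RESTRICTIONS,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
    k: int = 3,
) -> list[IndividualPrediction]:
    """Vectorised cause assignment for a batch of records."""
    schema = SymptomSchema(tariffs.symptoms)
    y = endorsement_array(records, schema)
    scores = score_matrix(y, tariffs)
    ranks = _rank_matrix(scores, baseline)
    m = baseline.size
    rank_limit = policy.rank_quantile_cutoff * m
    cap_limit = policy.overall_rank_cap * m

    out: list[IndividualPrediction] = []
    for i, r in enumerate(records):
        eligible = restrictions.eligibility_vector(tariffs.causes, r.sex, r.age_years)
        order = _candidate_order(scores[i], ranks[i], eligible)
        top = tuple(
            TopCause(tariffs.causes[j], float(scores[i, j]), int(ranks[i, j]))
            for j in order[:k]
        )
        if order.size == 0:
            assigned = UNDETERMINED
        else:
            best = order[0]
            undetermined = (
                ranks[i, best] > rank_limit
                or scores[i, best] < policy.minimum_score
                or ranks[i, best] > cap_limit
            )
            assigned = UNDETERMINED if undetermined else tariffs.causes[best]
        out.append(
            IndividualPrediction(
                record_id=r.record_id,
                assigned_cause=assigned,
                top_k=top,
                age_group=bin_age(r.age_years, scheme),
                sex=r.sex,
            )
        )
    return out


def assign_cause(
    record: VARecord,
    tariffs: TariffMatrix,
    baseline: RankBaseline,
    policy: CutoffPolicy = CutoffPolicy(),
    restrictions: CauseRestrictions = NO_RESTRICTIONS,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
    k: int = 3,
) -> IndividualPrediction:
    """Assign a single record (see :func:`assign_all`)."""
    return assign_all([record], tariffs, baseline, policy, restrictions, scheme, k)[0]


def top_k_causes(
    record: VARecord,
    tariffs: TariffMatrix,
    baseline: RankBaseline,
    k: int = 3,
    restrictions: CauseRestrictions = NO_RESTRICTIONS,
) -> tuple[TopCause, ...]:
    """The k best-ranked eligible causes for a record, for decision support.

    This is the physician-facing output: the top candidates with their
    scores and ranks, ignoring the undetermined rules.  If fewer than k
    causes are eligible, all eligible causes are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pred = assign_all([record], tariffs, baseline, NO_CUTOFFS, restrictions, k=k)[0]
    return pred.top_k


@dataclass(frozen=True)
class PipelineModel:
    """A trained assignment model: tariffs plus rank baseline."""

    schema: SymptomSchema
    causes: CauseList
    tariffs: TariffMatrix
    baseline: RankBaseline


def train_model(
    db: Sequence,
    schema: SymptomSchema,
    causes: CauseList,
    rounding_step: float | None = 0.5,
    truncation_rank: int | None = 40,
    per_cause_n: int = 100,
    seed: int = 0,
) -> PipelineModel:
    """Fit endorsement rates, tariffs and the rank baseline in one step."""
    x = compute_endorsement_rates(db, schema, causes)
    tariffs = compute_tariffs(x, rounding_step=rounding_step, truncation_rank=truncation_rank)
    baseline = build_rank_baseline(db, tariffs, per_cause_n=per_cause_n, seed=seed)
    return PipelineModel(schema, causes, tariffs, baseline)
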