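"""Population-level redistribution of undetermined deaths.

Undetermined deaths are not discarded: at the population level their mass is
reallocated across assignable causes using the average of two weight
vectors.

* **Fractional weights** reflect how likely each cause is to end up
  undetermined: some conditions (classically pneumonia) are inherently hard
  to diagnose from a verbal autopsy interview, while e.g. road-traffic
  deaths rarely are.  The weights are proportional to the per-cause rate at
  which gold-standard deaths of that cause are assigned undetermined when
  run through the trained pipeline (estimated by stratified k-fold
  cross-validation by default, to avoid resubstitution bias).

* **Reference weights** are the cause fractions of an external age-sex
  reference distribution (GBD-style) for the stratum of the death,
  renormalised over the causes the pipeline can assign.

The two are combined per (sex, age-group) stratum as
``lambda * w_frac + (1 - lambda) * w_ref`` with ``lambda = 0.5`` by default
(the unweighted mean), and the stratum's undetermined count is spread over
causes in those proportions.  Individual predictions are never altered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assignment import (
    NO_RESTRICTIONS,
    CauseRestrictions,
    CutoffPolicy,
    assign_all,
    train_model,
)
from .schema import (
    DEFAULT_AGE_SCHEME,
    UNDETERMINED,
    AgeGroupScheme,
    CauseList,
    ReferenceDistribution,
    SymptomSchema,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FractionalWeights:
    """Normalised undetermined-propensity weights with their provenance."""

    causes: tuple[str, ...]
    w: np.ndarray
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if np.any(w < 0):
            raise ValueError("fractional weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractional weights sum to {w.sum()!r}, expected 1")


def weights_from_undetermined_rates(
    rates: Sequence[float], causes: Sequence[str], provenance: Mapping[str, object] | None = None
) -> FractionalWeights:
    """Normalise per-cause undetermined rates into fractional weights.

    If no cause is ever undetermined the weights are undefined; fall back to
    uniform with a logged warning rather than failing the run.
    """
    rates = np.asarray(rates, dtype=float)
    total = rates.sum()
    prov = dict(provenance or {})
    if total <= 0:
        msg = "no gold-standard record was assigned undetermined; falling back to uniform fractional weights"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        w = np.full(len(rates), 1.0 / len(rates))
        prov["fallback"] = "uniform"
    else:
        w = rates / total
    return FractionalWeights(tuple(causes), w, prov)


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index folds with each cause spread across folds as evenly as possible."""
    assignments = [list() for _ in range(folds)]
    for cause in np.unique(labels):
        idx = np.flatnonzero(labels == cause)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignments[pos % folds].append(i)
    return [np.array(sorted(a), dtype=int) for a in assignments]


def fractional_weights(
    db: Sequence,
    schema: SymptomSchema,
    causes: CauseList,
    policy: CutoffPolicy = CutoffPolicy(),
    restrictions: CauseRestrictions = NO_RESTRICTIONS,
    method: str = "cv",
    folds: int = 5,
    rounding_step: float | None = 0.5,
    truncation_rank: int | None = 40,
    per_cause_n: int = 100,
    seed: int = 0,
) -> FractionalWeights:
    """Estimate undetermined-propensity weights from the gold standard.

    ``method="cv"`` (default) runs stratified ``folds``-fold
    cross-validation: each fold is assigned by a model trained on the other
    folds.  ``method="insample"`` trains on and assigns the full database
    (cheaper, but optimistic about determinability).
    """
    labels = np.array([r.true_cause for r in db])
    cause_ids = causes.assignable
    n_per_cause = np.array([(labels == c).sum() for c in cause_ids], dtype=float)
    if np.any(n_per_cause == 0):
        missing = [c for c, n in zip(cause_ids, n_per_cause) if n == 0]
        raise ValueError(f"gold standard has no records for causes {missing}")
    undet = np.zeros(len(cause_ids), dtype=float)

    if method == "insample":
        model = train_model(
            db, schema, causes,
            rounding_step=rounding_step, truncation_rank=truncation_rank,
            per_cause_n=per_cause_n, seed=seed,
        )
        preds = assign_all(db, model.tariffs, model.baseline, policy, restrictions)
        for r, p in zip(db, preds):
            if p.assigned_cause == UNDETERMINED:
                undet[cause_ids.index(r.true_cause)] += 1
    elif method == "cv":
        if folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")
        rng = np.random.default_rng(seed)
        fold_idx = _stratified_folds(labels, folds, rng)
        db_arr = np.array(db, dtype=object)
        for f, held_out in enumerate(fold_idx):
            if held_out.size == 0:
                continue
            train_idx = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            model = train_model(
                list(db_arr[train_idx]), schema, causes,
                rounding_step=rounding_step, truncation_rank=truncation_rank,
                per_cause_n=per_cause_n, seed=seed + 1 + f,
            )
            held = list(db_arr[held_out])
            preds = assign_all(held, model.tariffs, model.baseline, policy, restrictions)
            for r, p in zip(held, preds):
                if p.assigned_cause == UNDETERMINED:
                    undet[cause_ids.index(r.true_cause)] += 1
    else:
        raise ValueError(f"unknown method {method!r}; expected 'cv' or 'insample'")

    rates = undet / n_per_cause
    provenance = {
        "method": method,
        "undetermined_counts": {c: int(k) for c, k in zip(cause_ids, undet)},
        "training_counts": {c: int(k) for c, k in zip(cause_ids, n_per_cause)},
        "seed": seed,
    }
    return weights_from_undetermined_rates(rates, cause_ids, provenance)


def reference_weights(
    ref: ReferenceDistribution,
    sex: str,
    age_group: str,
    causes: CauseList,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> np.ndarray:
    """Reference cause fractions for a stratum, renormalised over VA causes.

    Fallbacks: unknown sex averages the male and female strata; unknown age
    group averages over the scheme's known age bins (an all-age marginal).
    A missing stratum with no applicable fallback raises ``KeyError`` naming
    the stratum.
    """
    if sex == "unknown":
        male = reference_weights(ref, "male", age_group, causes, scheme)
        female = reference_weights(ref, "female", age_group, causes, scheme)
        w = (male + female) / 2
        return w / w.sum()
    if age_group == scheme.unknown_label:
        parts = [
            reference_weights(ref, sex, label, causes, scheme)
            for label, _, _ in scheme.bins
            if (sex, label) in ref
        ]
        if not parts:
            raise KeyError(f"reference has no strata for sex={sex!r} to marginalise over")
        w = np.mean(parts, axis=0)
        return w / w.sum()
    fracs = ref.stratum(sex, age_group)
    w = np.array([float(fracs.get(c, 0.0)) for c in causes.assignable])
    total = w.sum()
    if total <= 0:
        # Reference puts no mass on any assignable cause in this stratum;
        # fall back to uniform so the stratum can still be redistributed.
        logger.warning(
            "reference stratum (%s, %s) has zero mass on assignable causes; using uniform",
            sex, age_group,
        )
        return np.full(len(causes.assignable), 1.0 / len(causes.assignable))
    return w / total


@dataclass(frozen=True)
class RedistributionResult:
    """Fractional death counts allocated from undetermined, per stratum."""

    causes: tuple[str, ...]
    per_stratum: Mapping[tuple[str, str], dict]  # stratum -> weight/count detail
    added: np.ndarray  # population totals per cause
    total_redistributed: float

    def added_by_cause(self) -> dict[str, float]:
        return {c: float(a) for c, a in zip(self.causes, self.added)}


def combine_weights(w_frac: np.ndarray, w_ref: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Mix fractional and reference weights and renormalise.

    ``lam = 1`` is pure fractional, ``lam = 0`` pure reference, ``0.5`` the
    unweighted mean of the two.
    """
    if not (0 <= lam <= 1):
        raise ValueError("mixing parameter must lie in [0, 1]")
    combined = lam * np.asarray(w_frac, float) + (1 - lam) * np.asarray(w_ref, float)
    total = combined.sum()
    if total <= 0:
        raise ValueError("combined weights sum to zero")
    return combined / total


def redistribute(
    undetermined_counts: Mapping[tuple[str, str], float],
    w_frac: FractionalWeights,
    ref: ReferenceDistribution,
    causes: CauseList,
    lam: float = 0.5,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> RedistributionResult:
    """Allocate per-stratum undetermined counts across causes.

    For each (sex, age-group) stratum the combined weight vector is applied
    to that stratum's undetermined count; stratum allocations are summed
    into population totals.  Total mass is conserved.
    """
    cause_ids = causes.assignable
    added = np.zeros(len(cause_ids), dtype=float)
    per_stratum: dict[tuple[str, str], dict] = {}
    total = 0.0
    for stratum, count in undetermined_counts.items():
        if count < 0:
            raise ValueError(f"negative undetermined count in stratum {stratum}")
        if count == 0:
            continue
        sex, age_group = stratum
        w_ref = reference_weights(ref, sex, age_group, causes, scheme)
        combined = combine_weights(w_frac.w, w_ref, lam)
        allocation = combined * count
        added += allocation
        total += count
        per_stratum[stratum] = {
            "n_undetermined": float(count),
            "w_frac": w_frac.w.copy(),
            "w_ref": w_ref,
            "combined": combined,
            "added": allocation,
        }
    return RedistributionResult(cause_ids, per_stratum, added, total)


def undetermined_counts_by_stratum(predictions: Sequence) -> dict[tuple[str, str], int]:
    """Count undetermined predictions per (sex, age-group) stratum."""
    counts: dict[tuple[str, str], int] = {}
    for p in predictions:
        if p.assigned_cause == UNDETERMINED:
            key = (p.sex, p.age_group)
            counts[key] = counts.get(key, 0) + 1
    return counts


def ranking_stable(
    before: Mapping[str, float], after: Mapping[str, float]
) -> bool:
    """Whether causes keep the same order before and after redistribution.

    Compares the cause ordering (by descending fraction, excluding the
    undetermined category) of the two CSMF vectors.  Reported, not assumed:
    redistribution usually preserves the ranking but is not guaranteed to.
    """
    keys = [c for c in before if c != UNDETERMINED]
    order_before = sorted(keys, key=lambda c: (-before[c], c))
    order_after = sorted(keys, key=lambda c: (-after.get(c, 0.0), c))
    return order_before == order_after
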