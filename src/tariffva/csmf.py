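"""Cause-specific mortality fractions (CSMFs) with bootstrap uncertainty.

The population-level output of the pipeline: the fraction of deaths
attributed to each cause, reported both before redistribution (with the
undetermined category as its own entry) and after redistribution (with the
undetermined mass reallocated and that category at zero).  Uncertainty is a
percentile bootstrap over deaths: resample the predictions with
replacement, redo the redistribution arithmetic per replicate, and take
empirical quantiles of the after-redistribution fractions.

Also implements chance-corrected CSMF accuracy,

    1 - sum_c |true_c - pred_c| / (2 (1 - min_c true_c)),

the standard population-level agreement metric for validating verbal
autopsy methods: 1 means exact agreement, 0 the worst attainable error for
that true distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .redistribution import (
    FractionalWeights,
    RedistributionResult,
    combine_weights,
    reference_weights,
)
from .schema import (
    DEFAULT_AGE_SCHEME,
    UNDETERMINED,
    AgeGroupScheme,
    BroadGroupMap,
    CauseList,
    ReferenceDistribution,
)


@dataclass(frozen=True)
class CSMFTable:
    """Per-category death counts and fractions, before/after redistribution.

    ``categories`` is the assignable cause list followed by the undetermined
    category.  ``fraction_after`` is ``None`` until redistribution has been
    applied; CI bounds are ``None`` until a bootstrap has been run.
    """

    categories: tuple[str, ...]
    counts: np.ndarray
    n_deaths: int
    fraction_after: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def fraction_before(self) -> np.ndarray:
        return self.counts / self.n_deaths

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(c for c in self.categories if c != UNDETERMINED)

    @property
    def undetermined_count(self) -> float:
        return float(self.counts[self.categories.index(UNDETERMINED)])

    def before_mapping(self) -> dict[str, float]:
        return dict(zip(self.categories, self.fraction_before))

    def after_mapping(self) -> dict[str, float]:
        if self.fraction_after is None:
            raise ValueError("redistribution has not been applied")
        return dict(zip(self.categories, self.fraction_after))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "cause": self.categories,
            "n_assigned": self.counts,
            "fraction_before": self.fraction_before,
        }
        if self.fraction_after is not None:
            data["fraction_after"] = self.fraction_after
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        return pd.DataFrame(data)


def aggregate(predictions: Sequence, causes: CauseList) -> CSMFTable:
    """Count assigned causes into a before-redistribution CSMF table."""
    if not len(predictions):
        raise ValueError("cannot aggregate an empty prediction set")
    categories = causes.all_ids
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros(len(categories), dtype=float)
    for p in predictions:
        counts[index[p.assigned_cause]] += 1
    return CSMFTable(categories, counts, len(predictions))


def csmf_after_redistribution(table: CSMFTable, result: RedistributionResult) -> CSMFTable:
    """Fold redistributed undetermined mass into the after fractions."""
    if abs(result.total_redistributed - table.undetermined_count) > 1e-6:
        raise ValueError(
            f"redistribution covered {result.total_redistributed} undetermined deaths "
            f"but the table has {table.undetermined_count}"
        )
    added = dict(zip(result.causes, result.added))
    after = np.zeros(len(table.categories), dtype=float)
    for i, c in enumerate(table.categories):
        if c == UNDETERMINED:
            after[i] = 0.0
        else:
            after[i] = (table.counts[i] + added.get(c, 0.0)) / table.n_deaths
    return replace(table, fraction_after=after)


def broad_group_fractions(
    table: CSMFTable, group_map: BroadGroupMap
) -> pd.DataFrame:
    """Sum cause fractions into broad cause groups.

    Before redistribution the undetermined category is kept as its own row
    (mirroring how before-redistribution bars are usually presented);
    after redistribution the groups alone sum to 1.
    """
    for c in table.causes:
        group_map.group_of(c)  # raises on unmapped causes
    groups = list(group_map.groups)
    rows = []
    before = table.before_mapping()
    after = table.after_mapping() if table.fraction_after is not None else None
    for g in groups:
        members = [c for c in table.causes if group_map.group_of(c) == g]
        row = {"group": g, "fraction_before": sum(before[c] for c in members)}
        if after is not None:
            row["fraction_after"] = sum(after[c] for c in members)
        rows.append(row)
    undet_row = {"group": UNDETERMINED, "fraction_before": before[UNDETERMINED]}
    if after is not None:
        undet_row["fraction_after"] = 0.0
    rows.append(undet_row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile-bootstrap CIs for after-redistribution fractions."""

    categories: tuple[str, ...]
    ci_low: np.ndarray
    ci_high: np.ndarray
    group_ci: Mapping[str, tuple[float, float]]
    replicates: np.ndarray  # (B, n_categories) after-redistribution fractions
    metadata: Mapping[str, object]


def bootstrap_ci(
    predictions: Sequence,
    causes: CauseList,
    w_frac: FractionalWeights,
    ref: ReferenceDistribution,
    lam: float = 0.5,
    group_map: BroadGroupMap | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> BootstrapResult:
    """Bootstrap deaths with replacement and redo redistribution per replicate.

    Each replicate resamples the n predictions, recounts causes and
    per-stratum undetermined deaths, reapplies the (fixed) combined weights,
    and records the after-redistribution fractions.  CIs are the empirical
    ``alpha/2`` and ``1 - alpha/2`` quantiles.
    """
    if B < 100:
        raise ValueError("bootstrap needs at least 100 replicates")
    n = len(predictions)
    categories = causes.all_ids
    cat_index = {c: i for i, c in enumerate(categories)}
    undet_idx = cat_index[UNDETERMINED]
    n_cat = len(categories)

    assigned = np.array([cat_index[p.assigned_cause] for p in predictions], dtype=np.int64)

    # Precompute the combined weight vector for every stratum present among
    # undetermined predictions; the weights are inputs, not resampled.
    strata: dict[tuple[str, str], int] = {}
    strata_weights: list[np.ndarray] = []
    record_stratum = np.full(n, -1, dtype=np.int64)
    for i, p in enumerate(predictions):
        if p.assigned_cause != UNDETERMINED:
            continue
        key = (p.sex, p.age_group)
        if key not in strata:
            strata[key] = len(strata_weights)
            w_ref = reference_weights(ref, key[0], key[1], causes, scheme)
            strata_weights.append(combine_weights(w_frac.w, w_ref, lam))
        record_stratum[i] = strata[key]
    weight_matrix = (
        np.vstack(strata_weights) if strata_weights else np.zeros((0, len(causes.assignable)))
    )

    rng = np.random.default_rng(seed)
    replicates = np.empty((B, n_cat), dtype=float)
    cause_slice = [cat_index[c] for c in causes.assignable]
    for b in range(B):
        sample = rng.integers(0, n, size=n)
        counts = np.bincount(assigned[sample], minlength=n_cat).astype(float)
        strat = record_stratum[sample]
        strat = strat[strat >= 0]
        after = counts.copy()
        if strat.size and weight_matrix.shape[0]:
            undet_per_stratum = np.bincount(strat, minlength=weight_matrix.shape[0]).astype(float)
            after[cause_slice] += undet_per_stratum @ weight_matrix
        after[undet_idx] = 0.0
        replicates[b] = after / n

    lo = np.quantile(replicates, alpha / 2, axis=0)
    hi = np.quantile(replicates, 1 - alpha / 2, axis=0)

    group_ci: dict[str, tuple[float, float]] = {}
    if group_map is not None:
        for g in group_map.groups:
            member_idx = [
                cat_index[c] for c in causes.assignable if group_map.group_of(c) == g
            ]
            g_reps = replicates[:, member_idx].sum(axis=1)
            group_ci[g] = (
                float(np.quantile(g_reps, alpha / 2)),
                float(np.quantile(g_reps, 1 - alpha / 2)),
            )

    return BootstrapResult(
        categories=categories,
        ci_low=lo,
        ci_high=hi,
        group_ci=group_ci,
        replicates=replicates,
        metadata={"B": B, "alpha": alpha, "seed": seed, "method": "percentile"},
    )


def attach_ci(table: CSMFTable, boot: BootstrapResult) -> CSMFTable:
    if boot.categories != table.categories:
        raise ValueError("bootstrap categories do not match the CSMF table")
    meta = dict(table.metadata)
    meta.update(boot.metadata)
    return replace(table, ci_low=boot.ci_low, ci_high=boot.ci_high, metadata=meta)


def csmf_accuracy(
    true_csmf: Mapping[str, float] | Sequence[float],
    predicted_csmf: Mapping[str, float] | Sequence[float],
) -> float:
    """Chance-corrected CSMF accuracy between two cause-fraction vectors.

    Both vectors must cover the same causes and sum to 1.  Equals 1 iff the
    distributions are identical; 0 when all predicted mass sits on the
    cause the truth considers rarest (the worst attainable error).
    """
    if isinstance(true_csmf, Mapping):
        if not isinstance(predicted_csmf, Mapping):
            raise TypeError("both CSMF arguments must be mappings or both sequences")
        keys = sorted(true_csmf)
        if sorted(predicted_csmf) != keys:
            raise ValueError("true and predicted CSMFs cover different causes")
        t = np.array([true_csmf[k] for k in keys], dtype=float)
        p = np.array([predicted_csmf[k] for k in keys], dtype=float)
    else:
        t = np.asarray(true_csmf, dtype=float)
        p = np.asarray(predicted_csmf, dtype=float)
        if t.shape != p.shape:
            raise ValueError("true and predicted CSMFs have different lengths")
    for name, v in (("true", t), ("predicted", p)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} CSMF sums to {v.sum()!r}, expected 1")
    denom = 2 * (1 - t.min())
    if denom == 0:
        # Single-cause truth: only exact agreement counts.
        return 1.0 if np.allclose(t, p, atol=1e-12) else 0.0
    return float(1 - np.abs(t - p).sum() / denom)
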