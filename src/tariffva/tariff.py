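"""Tariff score computation from a gold-standard training database.

The tariff for a symptom-cause pair measures how unusually often deaths of
that cause endorse the symptom, relative to all other causes:

    tariff(c, s) = (x[c, s] - median_c' x[c', s]) / IQR_c' x[c', s]

where ``x`` is the endorsement-rate matrix (fraction of gold-standard deaths
of each cause whose interview answered "yes" to each symptom).  The median
and interquartile range are taken across causes, per symptom, with linear
interpolation between order statistics.  A symptom whose endorsement rate is
identical across causes carries no diagnostic signal and gets a zero column
(this also covers the degenerate IQR = 0 case).

Two optional, on-by-default post-processing steps mirror common field
practice and are recorded in the matrix metadata: rounding scores to the
nearest 0.5 (midpoint ties round away from zero), and truncating each
cause's row to its K = 40 largest-|tariff| symptoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .schema import CauseList, SymptomSchema, VARecord

QUANTILE_METHOD = "linear"  # inclusive linear interpolation between order stats


@dataclass(frozen=True)
class EndorsementMatrix:
    """Per cause x symptom endorsement rates with training counts."""

    causes: tuple[str, ...]
    symptoms: tuple[str, ...]
    x: np.ndarray  # shape (n_causes, n_symptoms), entries in [0, 1]
    n: np.ndarray  # shape (n_causes,), training records per cause

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        if x.shape != (len(self.causes), len(self.symptoms)):
            raise ValueError(
                f"endorsement matrix shape {x.shape} does not match "
                f"{len(self.causes)} causes x {len(self.symptoms)} symptoms"
            )
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("endorsement rates must lie in [0, 1]")


@dataclass(frozen=True)
class TariffMatrix:
    """Tariff scores per cause x symptom, with provenance metadata."""

    causes: tuple[str, ...]
    symptoms: tuple[str, ...]
    t: np.ndarray  # shape (n_causes, n_symptoms)
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if not np.all(np.isfinite(t)):
            raise ValueError("tariff scores must be finite")

    def row(self, cause_id: str) -> np.ndarray:
        return self.t[self.causes.index(cause_id)]


def endorsement_array(records: Sequence[VARecord], schema: SymptomSchema) -> np.ndarray:
    """Binary (n_records x n_symptoms) matrix of "yes" endorsements.

    Missing responses count as not endorsed; this is the scoring-time view
    of the data, the records themselves keep the missing marker.
    """
    idx = schema.index()
    y = np.zeros((len(records), len(schema)), dtype=np.uint8)
    for i, r in enumerate(records):
        for sid, value in r.endorsements.items():
            if value == "yes":
                j = idx.get(sid)
                if j is not None:
                    y[i, j] = 1
    return y


def compute_endorsement_rates(
    db: Sequence, schema: SymptomSchema, causes: CauseList
) -> EndorsementMatrix:
    """Endorsement rate x[c, s] = (# cause-c deaths endorsing s) / n[c]."""
    y = endorsement_array(db, schema)
    labels = np.array([r.true_cause for r in db])
    x = np.zeros((len(causes), len(schema)), dtype=float)
    n = np.zeros(len(causes), dtype=int)
    for i, cause in enumerate(causes.assignable):
        mask = labels == cause
        n[i] = int(mask.sum())
        if n[i] == 0:
            raise ValueError(f"cause {cause!r} has no training records")
        x[i] = y[mask].mean(axis=0)
    return EndorsementMatrix(causes.assignable, schema.symptom_ids, x, n)


def round_to_step(t: np.ndarray, step: float) -> np.ndarray:
    """Round to the nearest multiple of ``step``; midpoint ties go away from zero."""
    scaled = np.abs(t) / step
    return np.sign(t) * np.floor(scaled + 0.5) * step


def truncate_rows(t: np.ndarray, k: int) -> np.ndarray:
    """Keep each row's k largest-|t| entries, zeroing the rest.

    Ties at the cut are broken by symptom order (earlier columns kept),
    which makes the operation deterministic.
    """
    if k >= t.shape[1]:
        return t.copy()
    out = np.zeros_like(t)
    for i in range(t.shape[0]):
        keep = np.argsort(-np.abs(t[i]), kind="stable")[:k]
        out[i, keep] = t[i, keep]
    return out


def compute_tariffs(
    x: EndorsementMatrix,
    rounding_step: float | None = 0.5,
    truncation_rank: int | None = 40,
) -> TariffMatrix:
    """Tariff matrix from endorsement rates via per-symptom median/IQR scaling.

    Parameters
    ----------
    x
        Endorsement-rate matrix; needs at least 3 causes for the median and
        IQR across causes to be meaningful.
    rounding_step
        Round scores to the nearest multiple of this step (``None`` disables).
    truncation_rank
        Keep only this many largest-|tariff| symptoms per cause
        (``None`` disables).
    """
    if len(x.causes) < 3:
        raise ValueError(
            f"tariff computation needs at least 3 causes, got {len(x.causes)}"
        )
    med = np.median(x.x, axis=0)
    q75, q25 = np.percentile(x.x, [75, 25], axis=0, method=QUANTILE_METHOD)
    iqr = q75 - q25
    t = np.zeros_like(x.x)
    nz = iqr > 0
    t[:, nz] = (x.x[:, nz] - med[nz]) / iqr[nz]
    if rounding_step:
        t = round_to_step(t, rounding_step)
    if truncation_rank is not None:
        t = truncate_rows(t, truncation_rank)
    metadata = {
        "rounding_step": rounding_step,
        "truncation_rank": truncation_rank,
        "quantile_method": QUANTILE_METHOD,
        "significance_filtering": "unavailable",
        "training_n": {c: int(k) for c, k in zip(x.causes, x.n)},
    }
    return TariffMatrix(x.causes, x.symptoms, t, metadata)


def score_matrix(endorsements: np.ndarray, tariffs: TariffMatrix) -> np.ndarray:
    """Scores (n_records x n_causes): sum of tariffs over endorsed symptoms."""
    return endorsements.astype(float) @ tariffs.t.T


def score_record(record: VARecord, tariffs: TariffMatrix) -> dict[str, float]:
    """Per-cause tariff score for one record (sum over "yes" endorsements)."""
    schema = SymptomSchema(tariffs.symptoms)
    y = endorsement_array([record], schema)
    scores = score_matrix(y, tariffs)[0]
    return {c: float(s) for c, s in zip(tariffs.causes, scores)}
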