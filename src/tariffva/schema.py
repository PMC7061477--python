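"""Domain types for verbal-autopsy (VA) records and vocabularies.

A VA interview is a structured, symptom-based questionnaire administered to
the caretakers of a deceased person.  The types here fix the shared
vocabulary for a pipeline run: the ordered symptom schema, the cause list
(with a reserved ``undetermined`` output category that is never a training
label), adult age groups, the mapping of causes to the three broad
cause-of-death groups, and a reference age-sex-cause distribution used for
redistribution and plausibility checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: Reserved output category: no cause could be assigned with sufficient
#: certainty.  Never a training label and never a tariff-matrix row.
UNDETERMINED = "undetermined"

SEXES = ("male", "female", "unknown")
ENDORSEMENT_VALUES = ("yes", "no", "missing")

#: Broad cause-of-death groups (level 1): group1 communicable, maternal and
#: nutritional conditions; group2 non-communicable diseases; group3 injuries.
BROAD_GROUPS = ("group1", "group2", "group3")


class SchemaError(ValueError):
    """Raised when a vocabulary object violates its invariants."""


@dataclass(frozen=True)
class SymptomSchema:
    """Ordered list of symptom identifiers with optional display labels.

    The order is fixed for the life of a pipeline run; every matrix built
    downstream (endorsement rates, tariffs) uses this column order.
    """

    symptom_ids: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(self.symptom_ids)
        object.__setattr__(self, "symptom_ids", ids)
        if not ids:
            raise SchemaError("symptom schema must contain at least one symptom")
        if any(not s for s in ids):
            raise SchemaError("symptom ids must be non-empty strings")
        if len(set(ids)) != len(ids):
            raise SchemaError("symptom ids must be unique")

    def __len__(self) -> int:
        return len(self.symptom_ids)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symptom_ids)}

    def label(self, symptom_id: str) -> str:
        return self.labels.get(symptom_id, symptom_id)


@dataclass(frozen=True)
class CauseList:
    """Ordered list of assignable causes of death.

    ``undetermined`` is reserved as an output-only category: it appears in
    :attr:`all_ids` but is never an assignable (trainable) cause.
    """

    cause_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(self.cause_ids)
        object.__setattr__(self, "cause_ids", ids)
        if not ids:
            raise SchemaError("cause list must contain at least one cause")
        if UNDETERMINED in ids:
            raise SchemaError(
                f"{UNDETERMINED!r} is a reserved output category, not an assignable cause"
            )
        if len(set(ids)) != len(ids):
            raise SchemaError("cause ids must be unique")

    def __len__(self) -> int:
        return len(self.cause_ids)

    @property
    def assignable(self) -> tuple[str, ...]:
        return self.cause_ids

    @property
    def all_ids(self) -> tuple[str, ...]:
        """Assignable causes followed by the reserved undetermined category."""
        return self.cause_ids + (UNDETERMINED,)

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cause_ids)}


@dataclass(frozen=True)
class VARecord:
    """One VA interview: demographics plus binary symptom endorsements.

    ``age_years`` is ``None`` when unknown (unknown-age deaths are a real
    feature of field data and flow through every stage).  Missing symptom
    responses are preserved as ``"missing"`` in storage; scoring treats them
    as not endorsed.
    """

    record_id: str
    age_years: float | None
    sex: str
    endorsements: Mapping[str, str] = field(default_factory=dict)

    def endorsed(self, symptom_id: str) -> bool:
        return self.endorsements.get(symptom_id) == "yes"


@dataclass(frozen=True)
class GoldStandardRecord(VARecord):
    """A VA record whose true cause of death is reliably known."""

    true_cause: str = ""

    def __post_init__(self) -> None:
        if self.true_cause == UNDETERMINED:
            raise SchemaError("gold-standard records cannot be labelled undetermined")


@dataclass(frozen=True)
class AgeGroupScheme:
    """Disjoint, exhaustive integer-year age bins for adult deaths.

    Bins are closed on both printed endpoints (``(12, 19)`` means
    12 <= age <= 19); the final bin is open-ended.  A dedicated ``Unknown``
    bin catches missing ages.
    """

    bins: tuple[tuple[str, int, int | None], ...] = (
        ("12-19", 12, 19),
        ("20-29", 20, 29),
        ("30-39", 30, 39),
        ("40-49", 40, 49),
        ("50-59", 50, 59),
        ("60-69", 60, 69),
        ("70-79", 70, 79),
        ("80+", 80, None),
    )
    unknown_label: str = "Unknown"

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.bins:
            if prev_hi is not None and lo != prev_hi + 1:
                raise SchemaError("age bins must be contiguous and disjoint")
            if hi is not None and hi < lo:
                raise SchemaError(f"empty age bin {label!r}")
            prev_hi = hi
        if self.bins[-1][2] is not None:
            raise SchemaError("last age bin must be open-ended")

    @property
    def floor(self) -> int:
        return self.bins[0][1]

    @property
    def labels(self) -> tuple[str, ...]:
        """Bin labels in order, Unknown last."""
        return tuple(label for label, _, _ in self.bins) + (self.unknown_label,)


DEFAULT_AGE_SCHEME = AgeGroupScheme()


def bin_age(age_years: float | None, scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME) -> str:
    """Map an age in years (or ``None`` for unknown) to its age-group label.

    Ages are interpreted as completed integer years (fractional ages are
    floored).  Ages below the scheme floor are an error: such deaths belong
    to child/neonate questionnaire modules, not the adult pipeline.
    """
    if age_years is None:
        return scheme.unknown_label
    if isinstance(age_years, float) and math.isnan(age_years):
        return scheme.unknown_label
    age = int(math.floor(float(age_years)))
    if age < scheme.floor:
        raise ValueError(
            f"age {age_years!r} is below the adult module floor of {scheme.floor} years"
        )
    for label, lo, hi in scheme.bins:
        if age >= lo and (hi is None or age <= hi):
            return label
    raise AssertionError("unreachable: scheme bins are exhaustive")  # pragma: no cover


@dataclass(frozen=True)
class BroadGroupMap:
    """Total mapping from assignable causes to broad cause groups."""

    mapping: Mapping[str, str]

    def group_of(self, cause_id: str) -> str:
        try:
            return self.mapping[cause_id]
        except KeyError:
            raise KeyError(f"cause {cause_id!r} has no broad-group mapping") from None

    @property
    def groups(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.mapping.values())
        return tuple(seen)

    def check_total(self, causes: CauseList) -> None:
        missing = [c for c in causes.assignable if c not in self.mapping]
        if missing:
            raise SchemaError(f"causes without a broad-group mapping: {missing}")


@dataclass(frozen=True)
class ReferenceDistribution:
    """Age-sex-stratified cause fractions from an external reference.

    ``strata`` maps ``(sex, age_group)`` to a cause -> fraction mapping;
    each stratum is a probability vector over the reference's cause list
    (which may be wider than the VA cause list; renormalisation over
    assignable causes happens at redistribution time).
    """

    strata: Mapping[tuple[str, str], Mapping[str, float]]

    def __post_init__(self) -> None:
        for key, fracs in self.strata.items():
            total = float(sum(fracs.values()))
            if any(v < 0 for v in fracs.values()):
                raise SchemaError(f"negative fraction in reference stratum {key}")
            if abs(total - 1.0) > 1e-9:
                raise SchemaError(
                    f"reference stratum {key} fractions sum to {total!r}, expected 1"
                )

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.strata

    def stratum(self, sex: str, age_group: str) -> Mapping[str, float]:
        try:
            return self.strata[(sex, age_group)]
        except KeyError:
            raise KeyError(f"reference has no stratum (sex={sex!r}, age_group={age_group!r})") from None


@dataclass(frozen=True)
class Violation:
    """One validation problem tied to a record and field."""

    record_id: str
    field: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of validating a batch of records.

    Validation never raises: the report lists violations per record and the
    records that passed, and the caller decides whether to abort.
    """

    violations: list[Violation] = field(default_factory=list)
    valid_records: list[VARecord] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def invalid_ids(self) -> set[str]:
        return {v.record_id for v in self.violations}


def validate_records(
    records: Sequence[VARecord],
    schema: SymptomSchema,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> ValidationReport:
    """Check records against the symptom schema and demographic contracts.

    Flags unknown endorsement keys, invalid endorsement values, invalid sex,
    ages below the adult floor, and duplicate record ids (every record
    sharing a duplicated id is flagged).  Valid records pass through in
    input order.
    """
    known = set(schema.symptom_ids)
    report = ValidationReport()

    seen: dict[str, int] = {}
    for r in records:
        seen[r.record_id] = seen.get(r.record_id, 0) + 1
    duplicated = {rid for rid, n in seen.items() if n > 1}

    for r in records:
        bad = False
        if r.record_id in duplicated:
            report.violations.append(
                Violation(r.record_id, "record_id", f"duplicate record_id {r.record_id!r}")
            )
            bad = True
        if r.sex not in SEXES:
            report.violations.append(
                Violation(r.record_id, "sex", f"invalid sex {r.sex!r}; expected one of {SEXES}")
            )
            bad = True
        if r.age_years is not None and not (
            isinstance(r.age_years, float) and math.isnan(r.age_years)
        ):
            try:
                age_ok = float(r.age_years) >= scheme.floor
            except (TypeError, ValueError):
                age_ok = False
            if not age_ok:
                report.violations.append(
                    Violation(
                        r.record_id,
                        "age_years",
                        f"age {r.age_years!r} invalid or below the adult floor of {scheme.floor}",
                    )
                )
                bad = True
        for key, value in r.endorsements.items():
            if key not in known:
                report.violations.append(
                    Violation(r.record_id, "endorsements", f"unknown symptom id {key!r}")
                )
                bad = True
            if value not in ENDORSEMENT_VALUES:
                report.violations.append(
                    Violation(
                        r.record_id,
                        "endorsements",
                        f"invalid endorsement value {value!r} for symptom {key!r}",
                    )
                )
                bad = True
        if not bad:
            report.valid_records.append(r)
    return report
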