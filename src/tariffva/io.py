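"""CSV ingestion/serialisation, pipeline configuration and orchestration.

The ingestion boundary is flat CSV as exported by electronic
data-collection tools: one row per death, a mandatory header, UTF-8,
symptom endorsements coded 1/0/blank for yes/no/missing.  Outputs are CSVs
plus a plain-text plausibility report, each run stamped with the seed and a
hash of the configuration so results can be traced back to their inputs.

A :class:`StageCounts` ledger records how many deaths enter and leave each
stage (read, valid, assigned, undetermined, redistributed, plus any
caller-defined exclusion categories), so headline summary numbers — e.g.
what share of deaths the VA tool certified, or how many deaths a figure
excluded — are recomputable from the log alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assignment import CutoffPolicy, assign_all, train_model
from .csmf import (
    aggregate,
    attach_ci,
    bootstrap_ci,
    broad_group_fractions,
    csmf_after_redistribution,
)
from .plausibility import build_report
from .redistribution import (
    fractional_weights,
    ranking_stable,
    redistribute,
    undetermined_counts_by_stratum,
)
from .schema import (
    DEFAULT_AGE_SCHEME,
    UNDETERMINED,
    BroadGroupMap,
    CauseList,
    GoldStandardRecord,
    ReferenceDistribution,
    SymptomSchema,
    VARecord,
    ValidationReport,
    Violation,
    validate_records,
)
from .tariff import TariffMatrix

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("record_id", "age_years", "sex")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class StageCounts:
    """Named death counts recorded as the pipeline (or an analyst) proceeds."""

    counts: dict[str, float] = field(default_factory=dict)

    def record(self, name: str, value: float) -> None:
        self.counts[name] = float(value)

    def get(self, name: str) -> float:
        return self.counts[name]

    def fraction(self, numerator: str, denominator: str) -> float:
        denom = self.counts[denominator]
        if denom == 0:
            raise ZeroDivisionError(f"count {denominator!r} is zero")
        return self.counts[numerator] / denom

    def total(self, names: Sequence[str]) -> float:
        return float(sum(self.counts[n] for n in names))

    def to_json(self) -> str:
        return json.dumps(self.counts, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path: str | Path) -> pd.DataFrame:
    # pandas handles CRLF/LF transparently; keep blanks distinguishable.
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def _parse_endorsement(value: str) -> str:
    v = value.strip()
    if v == "1":
        return "yes"
    if v == "0":
        return "no"
    if v == "":
        return "missing"
    raise ValueError(f"endorsement cell must be 1, 0 or blank, got {value!r}")


def _parse_sex(value: str) -> str:
    v = value.strip().lower()
    if v in ("male", "female", "unknown"):
        return v
    if v == "":
        return "unknown"
    return value  # invalid; caught by validate_records


def read_records_csv(
    path: str | Path,
    schema: SymptomSchema,
    gold_standard: bool = False,
) -> tuple[list[VARecord], ValidationReport]:
    """Parse a records CSV against a symptom schema.

    Row-level problems (unparseable ages, bad endorsement codes) are
    collected into the returned :class:`ValidationReport` rather than
    aborting the read; structural problems (missing mandatory columns,
    symptom columns not in the schema) raise immediately.
    """
    df = _read_csv(path)
    mandatory = list(MANDATORY_COLUMNS) + (["true_cause"] if gold_standard else [])
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"records file {path} is missing mandatory column {col!r}")
    symptom_cols = [c for c in df.columns if c not in mandatory]
    unknown = [c for c in symptom_cols if c not in schema.symptom_ids]
    if unknown:
        raise ValueError(
            f"records file {path} has symptom columns not in the schema: {unknown}"
        )

    records: list[VARecord] = []
    report = ValidationReport()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        rid = row_d["record_id"]
        age_raw = row_d["age_years"].strip()
        age: float | None
        if age_raw == "":
            age = None
        else:
            try:
                age = float(age_raw)
            except ValueError:
                report.violations.append(
                    Violation(rid, "age_years", f"row {row_number}: unparseable age {age_raw!r}")
                )
                continue
        try:
            endorsements = {c: _parse_endorsement(row_d[c]) for c in symptom_cols}
        except ValueError as exc:
            report.violations.append(
                Violation(rid, "endorsements", f"row {row_number}: {exc}")
            )
            continue
        sex = _parse_sex(row_d["sex"])
        if gold_standard:
            records.append(
                GoldStandardRecord(
                    record_id=rid, age_years=age, sex=sex,
                    endorsements=endorsements, true_cause=row_d["true_cause"],
                )
            )
        else:
            records.append(
                VARecord(record_id=rid, age_years=age, sex=sex, endorsements=endorsements)
            )
    return records, report


def write_records_csv(
    path: str | Path, records: Sequence[VARecord], schema: SymptomSchema
) -> None:
    rows = []
    code = {"yes": "1", "no": "0", "missing": ""}
    for r in records:
        row: dict[str, object] = {
            "record_id": r.record_id,
            "age_years": "" if r.age_years is None else (
                int(r.age_years) if float(r.age_years).is_integer() else r.age_years
            ),
            "sex": r.sex,
        }
        if isinstance(r, GoldStandardRecord):
            row["true_cause"] = r.true_cause
        for s in schema.symptom_ids:
            row[s] = code[r.endorsements.get(s, "missing")]
        rows.append(row)
    columns = list(MANDATORY_COLUMNS)
    if any(isinstance(r, GoldStandardRecord) for r in records):
        columns.append("true_cause")
    columns.extend(schema.symptom_ids)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, encoding="utf-8")


def read_schema_csv(path: str | Path) -> SymptomSchema:
    df = _read_csv(path)
    if "symptom_id" not in df.columns:
        raise ValueError(f"schema file {path} is missing column 'symptom_id'")
    labels = (
        dict(zip(df["symptom_id"], df["label"])) if "label" in df.columns else {}
    )
    return SymptomSchema(tuple(df["symptom_id"]), labels)


def write_schema_csv(path: str | Path, schema: SymptomSchema) -> None:
    pd.DataFrame(
        {"symptom_id": schema.symptom_ids,
         "label": [schema.label(s) for s in schema.symptom_ids]}
    ).to_csv(path, index=False, encoding="utf-8")


def read_reference_csv(path: str | Path) -> ReferenceDistribution:
    df = _read_csv(path)
    for col in ("sex", "age_group", "cause_id", "fraction"):
        if col not in df.columns:
            raise ValueError(f"reference file {path} is missing column {col!r}")
    strata: dict[tuple[str, str], dict[str, float]] = {}
    for row in df.itertuples(index=False):
        strata.setdefault((row.sex, row.age_group), {})[row.cause_id] = float(row.fraction)
    return ReferenceDistribution(strata)


def write_reference_csv(path: str | Path, ref: ReferenceDistribution) -> None:
    rows = [
        {"sex": sex, "age_group": age_group, "cause_id": c, "fraction": repr(float(v))}
        for (sex, age_group), fracs in ref.strata.items()
        for c, v in fracs.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_broad_group_csv(path: str | Path) -> BroadGroupMap:
    df = _read_csv(path)
    for col in ("cause_id", "group"):
        if col not in df.columns:
            raise ValueError(f"broad-group file {path} is missing column {col!r}")
    return BroadGroupMap(dict(zip(df["cause_id"], df["group"])))


def write_broad_group_csv(path: str | Path, group_map: BroadGroupMap) -> None:
    pd.DataFrame(
        [{"cause_id": c, "group": g} for c, g in group_map.mapping.items()]
    ).to_csv(path, index=False, encoding="utf-8")


def write_tariff_csv(path: str | Path, tariffs: TariffMatrix) -> None:
    """Tariff matrix as CSV (rows causes) plus a key-value metadata sidecar."""
    df = pd.DataFrame(tariffs.t, index=list(tariffs.causes), columns=list(tariffs.symptoms))
    df.index.name = "cause_id"
    df.to_csv(path, encoding="utf-8")
    sidecar = Path(path).with_suffix(".meta.txt")
    with open(sidecar, "w", encoding="utf-8") as fh:
        for key, value in tariffs.metadata.items():
            fh.write(f"{key} = {json.dumps(value)}\n")


def read_tariff_csv(path: str | Path) -> TariffMatrix:
    df = pd.read_csv(path, index_col="cause_id", encoding="utf-8")
    metadata: dict[str, object] = {}
    sidecar = Path(path).with_suffix(".meta.txt")
    if sidecar.exists():
        for line in sidecar.read_text(encoding="utf-8").splitlines():
            if " = " in line:
                key, raw = line.split(" = ", 1)
                metadata[key] = json.loads(raw)
    return TariffMatrix(
        tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float), metadata
    )


def write_predictions_csv(path: str | Path, predictions: Sequence) -> None:
    rows = []
    for p in predictions:
        row: dict[str, object] = {
            "record_id": p.record_id,
            "assigned_cause": p.assigned_cause,
        }
        for i in range(3):
            if i < len(p.top_k):
                tc = p.top_k[i]
                row[f"cause{i + 1}"] = tc.cause_id
                row[f"score{i + 1}"] = tc.score
                row[f"rank{i + 1}"] = tc.rank
            else:
                row[f"cause{i + 1}"] = ""
                row[f"score{i + 1}"] = ""
                row[f"rank{i + 1}"] = ""
        row["age_group"] = p.age_group
        row["sex"] = p.sex
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_redistribution_csv(path: str | Path, result) -> None:
    rows = []
    for (sex, age_group), detail in result.per_stratum.items():
        for i, cause in enumerate(result.causes):
            rows.append(
                {
                    "sex": sex,
                    "age_group": age_group,
                    "cause_id": cause,
                    "w_frac": detail["w_frac"][i],
                    "w_ref": detail["w_ref"][i],
                    "combined": detail["combined"][i],
                    "added_count": detail["added"][i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration & end-to-end pipeline


@dataclass
class PipelineConfig:
    """Everything one batch run needs, serialisable to YAML."""

    schema_csv: str = "schema.csv"
    gold_csv: str = "gold.csv"
    records_csv: str = "records.csv"
    reference_csv: str = "reference.csv"
    broad_group_csv: str = "broad_groups.csv"
    reference_age_csv: str | None = None
    out_dir: str = "out"
    rank_quantile_cutoff: float = 0.89
    minimum_score: float = 0.0
    overall_rank_cap: float = 1.0
    rounding_step: float | None = 0.5
    truncation_rank: int | None = 40
    per_cause_n: int = 100
    redistribution_lambda: float = 0.5
    fractional_weight_method: str = "cv"
    cv_folds: int = 5
    bootstrap_B: int = 1000
    seed: int = 0

    def policy(self) -> CutoffPolicy:
        return CutoffPolicy(
            rank_quantile_cutoff=self.rank_quantile_cutoff,
            minimum_score=self.minimum_score,
            overall_rank_cap=self.overall_rank_cap,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineOutputs:
    predictions_csv: Path
    csmf_csv: Path
    groups_csv: Path
    redistribution_csv: Path
    plausibility_md: Path
    log_json: Path
    counts: StageCounts
    ranking_stable: bool


def run_pipeline(config: PipelineConfig) -> PipelineOutputs:
    """Execute train -> assign -> redistribute -> CSMF -> plausibility.

    All randomness derives from ``config.seed``; rerunning with the same
    inputs and seed reproduces every output byte for byte (outputs carry
    the config hash and seed instead of timestamps).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = StageCounts()

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    with stage("read"):
        schema = read_schema_csv(config.schema_csv)
        gold, gold_report = read_records_csv(config.gold_csv, schema, gold_standard=True)
        records, records_report = read_records_csv(config.records_csv, schema)
        ref = read_reference_csv(config.reference_csv)
        group_map = read_broad_group_csv(config.broad_group_csv)
        causes = CauseList(tuple(dict.fromkeys(r.true_cause for r in gold)))
        counts.record("gold_read", len(gold) + len(gold_report.invalid_ids()))
        counts.record("records_read", len(records) + len(records_report.invalid_ids()))

    with stage("validate"):
        report = validate_records(records, schema)
        records = report.valid_records
        counts.record("records_valid", len(records))
        if not records:
            raise ValueError("no valid records to analyse")

    with stage("train"):
        model = train_model(
            gold, schema, causes,
            rounding_step=config.rounding_step,
            truncation_rank=config.truncation_rank,
            per_cause_n=config.per_cause_n,
            seed=config.seed,
        )

    with stage("assign"):
        policy = config.policy()
        predictions = assign_all(records, model.tariffs, model.baseline, policy)
        counts.record("assigned", len(predictions))
        counts.record(
            "undetermined",
            sum(1 for p in predictions if p.assigned_cause == UNDETERMINED),
        )

    with stage("redistribute"):
        w_frac = fractional_weights(
            gold, schema, causes, policy,
            method=config.fractional_weight_method,
            folds=config.cv_folds,
            rounding_step=config.rounding_step,
            truncation_rank=config.truncation_rank,
            per_cause_n=config.per_cause_n,
            seed=config.seed + 10,
        )
        undet_strata = undetermined_counts_by_stratum(predictions)
        redist = redistribute(
            undet_strata, w_frac, ref, causes, lam=config.redistribution_lambda
        )
        counts.record("redistributed", redist.total_redistributed)

    with stage("csmf"):
        table = aggregate(predictions, causes)
        table = csmf_after_redistribution(table, redist)
        boot = bootstrap_ci(
            predictions, causes, w_frac, ref,
            lam=config.redistribution_lambda,
            group_map=group_map,
            B=config.bootstrap_B,
            seed=config.seed + 20,
        )
        table = attach_ci(table, boot)
        groups = broad_group_fractions(table, group_map)
        stable = ranking_stable(table.before_mapping(), table.after_mapping())

    with stage("plausibility"):
        group_ci = {
            g: (
                float(groups.set_index("group").loc[g, "fraction_after"]),
                *boot.group_ci[g],
            )
            for g in group_map.groups
        }
        ref_groups = _reference_group_fractions(ref, group_map, causes)
        ref_age = None
        if config.reference_age_csv:
            age_df = _read_csv(config.reference_age_csv)
            ref_age = dict(zip(age_df["age_group"], age_df["percent"].astype(float)))
        report_obj = build_report(
            records, predictions, group_ci, ref_groups, ref_age_percent=ref_age
        )

    with stage("write"):
        stamp = f"# config_hash={config.config_hash()} seed={config.seed}\n"
        predictions_csv = out_dir / "predictions.csv"
        write_predictions_csv(predictions_csv, predictions)
        csmf_csv = out_dir / "csmf.csv"
        table.to_frame().to_csv(csmf_csv, index=False, encoding="utf-8")
        groups_csv = out_dir / "groups.csv"
        groups.to_csv(groups_csv, index=False, encoding="utf-8")
        redistribution_csv = out_dir / "redistribution.csv"
        write_redistribution_csv(redistribution_csv, redist)
        plausibility_md = out_dir / "plausibility.md"
        plausibility_md.write_text(stamp + report_obj.render(), encoding="utf-8")
        log_json = out_dir / "log.json"
        log_payload = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "counts": counts.counts,
            "ranking_stable": stable,
        }
        log_json.write_text(json.dumps(log_payload, indent=2, sort_keys=True), encoding="utf-8")

    return PipelineOutputs(
        predictions_csv=predictions_csv,
        csmf_csv=csmf_csv,
        groups_csv=groups_csv,
        redistribution_csv=redistribution_csv,
        plausibility_md=plausibility_md,
        log_json=log_json,
        counts=counts,
        ranking_stable=stable,
    )


def _reference_group_fractions(
    ref: ReferenceDistribution, group_map: BroadGroupMap, causes: CauseList
) -> dict[str, float]:
    """All-strata mean reference fractions aggregated to broad groups."""
    from .redistribution import reference_weights

    vectors = []
    for sex, age_group in ref.strata:
        vectors.append(reference_weights(ref, sex, age_group, causes))
    mean = np.mean(vectors, axis=0)
    mean = mean / mean.sum()
    out: dict[str, float] = {g: 0.0 for g in group_map.groups}
    for c, v in zip(causes.assignable, mean):
        out[group_map.group_of(c)] += float(v)
    return out
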