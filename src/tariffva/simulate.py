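"""Synthetic gold-standard, field and reference data for the full pipeline.

Real gold-standard VA databases and country CRVS extracts are held under
restrictive licences, so every pipeline stage here is exercised on
synthetic data with a known generative model:

* Each cause owns a disjoint block of *signature* symptoms endorsed with
  probability ``signal``; every other symptom is endorsed at
  ``background_rate``.  Symptoms are independent given the cause (a naive
  generative model — enough to exercise every stage; symptom dependence is
  a documented extension point).
* Field deaths draw their cause from a configurable true CSMF, then age and
  sex from one of three demographic archetypes assigned to the cause
  (young-injury, mid-infectious, old-NCD), so age gradients by cause group
  resemble real mortality data qualitatively.
* The reference distribution is the analytic (sex, age-group)-stratified
  cause distribution implied by the same generative model, optionally
  perturbed by a controllable distortion so that discrepancy scenarios
  (a reference that disagrees with the field truth) can be constructed.

Defaults are the strong-signal study configuration used throughout the
test-bed: 10 causes with 3 signature symptoms each out of 40 symptoms,
signal 0.95 against background 0.05, 500 training records per cause and
5,000 field deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .schema import (
    DEFAULT_AGE_SCHEME,
    AgeGroupScheme,
    BroadGroupMap,
    CauseList,
    GoldStandardRecord,
    ReferenceDistribution,
    SymptomSchema,
    VARecord,
)
from .tariff import EndorsementMatrix


@dataclass(frozen=True)
class Archetype:
    """Demographic profile shared by causes of a broad group."""

    name: str
    group: str
    age_mean: float
    age_sd: float
    p_male: float


#: Three archetypes giving the qualitative age gradient of real mortality:
#: injuries hit young adults, infections the middle-aged, NCDs the old.
ARCHETYPES = (
    Archetype("young-injury", "group3", 32.0, 12.0, 0.70),
    Archetype("mid-infectious", "group1", 48.0, 15.0, 0.55),
    Archetype("old-ncd", "group2", 72.0, 12.0, 0.48),
)

AGE_CLIP = (12, 99)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study population.

    ``true_csmf`` defaults to a normalised geometric sequence (ratio 0.8),
    giving a realistic mix of common and rare causes without any cause
    being vanishingly rare at the default sample sizes.
    """

    n_causes: int = 10
    n_symptoms: int = 40
    signature_size: int = 3
    signal: float = 0.95
    background_rate: float = 0.05
    true_csmf: tuple[float, ...] | None = None
    n_train_per_cause: int = 500
    n_deaths: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_symptoms < self.n_causes:
            raise ValueError(
                "n_symptoms must be at least n_causes so each cause can own a signature block"
            )
        if self.n_symptoms < self.n_causes * self.signature_size:
            raise ValueError(
                f"{self.n_causes} causes x {self.signature_size} signature symptoms "
                f"need at least {self.n_causes * self.signature_size} symptoms, "
                f"got {self.n_symptoms}"
            )
        if not (0 <= self.background_rate < self.signal <= 1):
            raise ValueError("need 0 <= background_rate < signal <= 1")
        if self.true_csmf is not None:
            csmf = tuple(float(v) for v in self.true_csmf)
            if len(csmf) != self.n_causes:
                raise ValueError("true_csmf length must equal n_causes")
            if abs(sum(csmf) - 1.0) > 1e-9 or any(v < 0 for v in csmf):
                raise ValueError("true_csmf must be a probability vector")
            object.__setattr__(self, "true_csmf", csmf)

    @property
    def csmf(self) -> np.ndarray:
        if self.true_csmf is not None:
            return np.asarray(self.true_csmf, dtype=float)
        raw = 0.8 ** np.arange(self.n_causes)
        return raw / raw.sum()

    def cause_ids(self) -> tuple[str, ...]:
        return tuple(f"cause_{i + 1:02d}" for i in range(self.n_causes))

    def symptom_ids(self) -> tuple[str, ...]:
        return tuple(f"s{j + 1:02d}" for j in range(self.n_symptoms))

    def archetype_of(self, cause_index: int) -> Archetype:
        return ARCHETYPES[cause_index % len(ARCHETYPES)]


def symptom_schema(cfg: SimulationConfig) -> SymptomSchema:
    return SymptomSchema(cfg.symptom_ids())


def cause_list(cfg: SimulationConfig) -> CauseList:
    return CauseList(cfg.cause_ids())


def broad_group_map(cfg: SimulationConfig) -> BroadGroupMap:
    """Each cause inherits its archetype's broad group."""
    return BroadGroupMap(
        {c: cfg.archetype_of(i).group for i, c in enumerate(cfg.cause_ids())}
    )


def generating_matrix(cfg: SimulationConfig) -> EndorsementMatrix:
    """The true endorsement-probability matrix behind the simulator."""
    p = np.full((cfg.n_causes, cfg.n_symptoms), cfg.background_rate, dtype=float)
    for i in range(cfg.n_causes):
        lo = i * cfg.signature_size
        p[i, lo : lo + cfg.signature_size] = cfg.signal
    return EndorsementMatrix(
        cfg.cause_ids(),
        cfg.symptom_ids(),
        p,
        np.zeros(cfg.n_causes, dtype=int),
    )


def _sample_ages_sexes(
    cause_indices: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    n = len(cause_indices)
    means = np.array([cfg.archetype_of(i).age_mean for i in cause_indices])
    sds = np.array([cfg.archetype_of(i).age_sd for i in cause_indices])
    p_male = np.array([cfg.archetype_of(i).p_male for i in cause_indices])
    ages = np.clip(rng.normal(means, sds), *AGE_CLIP).astype(int)
    sexes = np.where(rng.random(n) < p_male, "male", "female").tolist()
    return ages, sexes


def _endorsements(
    cause_indices: np.ndarray,
    probs: np.ndarray,
    symptoms: tuple[str, ...],
    rng: np.random.Generator,
) -> list[dict[str, str]]:
    draws = rng.random((len(cause_indices), probs.shape[1])) < probs[cause_indices]
    return [
        {s: ("yes" if v else "no") for s, v in zip(symptoms, row)} for row in draws
    ]


def generate_gold_standard(
    cfg: SimulationConfig,
) -> tuple[list[GoldStandardRecord], EndorsementMatrix]:
    """Balanced labelled training database plus the generating matrix.

    Each cause contributes exactly ``n_train_per_cause`` records; ages and
    sexes follow the cause's archetype.  Reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = generating_matrix(cfg)
    cause_ids = cfg.cause_ids()
    cause_indices = np.repeat(np.arange(cfg.n_causes), cfg.n_train_per_cause)
    ages, sexes = _sample_ages_sexes(cause_indices, cfg, rng)
    endors = _endorsements(cause_indices, truth.x, cfg.symptom_ids(), rng)
    records = [
        GoldStandardRecord(
            record_id=f"gs-{i + 1:06d}",
            age_years=float(ages[i]),
            sex=sexes[i],
            endorsements=endors[i],
            true_cause=cause_ids[ci],
        )
        for i, ci in enumerate(cause_indices)
    ]
    truth_with_n = EndorsementMatrix(
        truth.causes,
        truth.symptoms,
        truth.x,
        np.full(cfg.n_causes, cfg.n_train_per_cause, dtype=int),
    )
    return records, truth_with_n


def generate_field_deaths(
    cfg: SimulationConfig,
) -> tuple[list[VARecord], pd.DataFrame]:
    """Field VA interviews with causes drawn from the true CSMF.

    Returns the records (cause hidden) and a truth table mapping record id
    to the true cause; the truth table is for evaluation only and must not
    reach the pipeline.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.n_deaths == 0:
        return [], pd.DataFrame(columns=["record_id", "true_cause"])
    cause_ids = cfg.cause_ids()
    cause_indices = rng.choice(cfg.n_causes, size=cfg.n_deaths, p=cfg.csmf)
    ages, sexes = _sample_ages_sexes(cause_indices, cfg, rng)
    probs = generating_matrix(cfg).x
    endors = _endorsements(cause_indices, probs, cfg.symptom_ids(), rng)
    records = [
        VARecord(
            record_id=f"va-{i + 1:06d}",
            age_years=float(ages[i]),
            sex=sexes[i],
            endorsements=endors[i],
        )
        for i in range(cfg.n_deaths)
    ]
    truth = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "true_cause": [cause_ids[ci] for ci in cause_indices],
        }
    )
    return records, truth


def _age_bin_probability(
    arch: Archetype, lo: int, hi: int | None, scheme: AgeGroupScheme
) -> float:
    """P(clipped, floored age lands in [lo, hi]) under the archetype's normal."""
    dist = norm(arch.age_mean, arch.age_sd)
    clip_lo, clip_hi = AGE_CLIP
    lower = -np.inf if lo <= clip_lo else float(lo)
    upper = np.inf if hi is None or hi >= clip_hi else float(hi + 1)
    return float(dist.cdf(upper) - dist.cdf(lower))


def stratified_truth(
    cfg: SimulationConfig, scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME
) -> dict[tuple[str, str], dict[str, float]]:
    """Exact (sex, age-group)-stratified cause fractions implied by the model.

    For each stratum, P(cause | stratum) is proportional to
    ``csmf[c] * P(sex | c) * P(age bin | c)`` computed in closed form from
    the archetype's clipped normal age model.
    """
    cause_ids = cfg.cause_ids()
    csmf = cfg.csmf
    strata: dict[tuple[str, str], dict[str, float]] = {}
    for sex in ("male", "female"):
        for label, lo, hi in scheme.bins:
            mass = np.zeros(cfg.n_causes)
            for i in range(cfg.n_causes):
                arch = cfg.archetype_of(i)
                p_sex = arch.p_male if sex == "male" else 1 - arch.p_male
                mass[i] = csmf[i] * p_sex * _age_bin_probability(arch, lo, hi, scheme)
            total = mass.sum()
            if total <= 0:
                continue
            strata[(sex, label)] = dict(zip(cause_ids, mass / total))
    return strata


def generate_reference(
    cfg: SimulationConfig,
    distortion: float = 0.0,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> ReferenceDistribution:
    """Reference distribution: the stratified truth, optionally distorted.

    ``distortion`` d >= 0 multiplies each stratum cause fraction by
    ``exp(d * u)`` with u ~ Uniform(-1, 1) (seeded from the config) before
    renormalising; d = 0 reproduces the truth exactly.
    """
    if distortion < 0:
        raise ValueError("distortion must be >= 0")
    strata = stratified_truth(cfg, scheme)
    if distortion == 0:
        return ReferenceDistribution(strata)
    rng = np.random.default_rng(cfg.seed + 2)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for key, fracs in strata.items():
        values = np.array(list(fracs.values()))
        factors = np.exp(distortion * rng.uniform(-1, 1, size=len(values)))
        perturbed = values * factors
        perturbed /= perturbed.sum()
        out[key] = dict(zip(fracs.keys(), perturbed))
    return ReferenceDistribution(out)


def shift_group_mass(
    ref: ReferenceDistribution,
    group_map: BroadGroupMap,
    source_group: str,
    target_group: str,
    amount: float,
) -> ReferenceDistribution:
    """Move a fraction of each stratum's mass between broad groups.

    Used to build discrepancy scenarios in which the reference over- or
    under-states a group relative to the field truth (e.g. a reference that
    overstates non-communicable disease mortality).  ``amount`` is the
    absolute probability mass moved per stratum, capped at what the source
    group holds; it is removed proportionally from source-group causes and
    added proportionally to target-group causes.
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    out: dict[tuple[str, str], dict[str, float]] = {}
    for key, fracs in ref.strata.items():
        fracs = dict(fracs)
        src = [c for c in fracs if group_map.group_of(c) == source_group]
        dst = [c for c in fracs if group_map.group_of(c) == target_group]
        src_mass = sum(fracs[c] for c in src)
        dst_mass = sum(fracs[c] for c in dst)
        move = min(amount, src_mass)
        if move > 0 and src_mass > 0 and dst:
            for c in src:
                fracs[c] -= move * fracs[c] / src_mass
            if dst_mass > 0:
                for c in dst:
                    fracs[c] += move * fracs[c] / dst_mass
            else:
                for c in dst:
                    fracs[c] += move / len(dst)
        # Guard against tiny negatives from floating-point cancellation when
        # a group's whole mass is moved out.
        fracs = {c: max(v, 0.0) for c, v in fracs.items()}
        total = sum(fracs.values())
        out[key] = {c: v / total for c, v in fracs.items()}
    return ReferenceDistribution(out)


def reference_age_percent(
    cfg: SimulationConfig, scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME
) -> dict[str, float]:
    """All-cause reference age distribution (percent per bin) implied by the
    generative model, for age-plausibility comparisons."""
    csmf = cfg.csmf
    percent: dict[str, float] = {}
    for label, lo, hi in scheme.bins:
        p = sum(
            csmf[i] * _age_bin_probability(cfg.archetype_of(i), lo, hi, scheme)
            for i in range(cfg.n_causes)
        )
        percent[label] = round(100.0 * float(p), 1)
    percent[scheme.unknown_label] = 0.0
    return percent
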