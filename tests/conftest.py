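import numpy as np
import pytest

from tariffva.schema import CauseList, GoldStandardRecord, SymptomSchema, VARecord


def make_record(rid, age, sex, yes=(), schema=None, cause=None):
    """Build a (gold-standard) record endorsing exactly the given symptoms."""
    endorsements = {}
    if schema is not None:
        endorsements = {s: ("yes" if s in yes else "no") for s in schema.symptom_ids}
    else:
        endorsements = {s: "yes" for s in yes}
    if cause is None:
        return VARecord(rid, age, sex, endorsements)
    return GoldStandardRecord(rid, age, sex, endorsements, true_cause=cause)


@pytest.fixture
def toy_schema():
    return SymptomSchema(("s1", "s2", "s3", "s4", "s5", "s6"))


@pytest.fixture
def toy_causes():
    return CauseList(("A", "B", "C"))


@pytest.fixture
def toy_gold(toy_schema):
    """Strong-signal toy database: each cause has two exclusive symptoms."""
    signature = {"A": ("s1", "s2"), "B": ("s3", "s4"), "C": ("s5", "s6")}
    records = []
    for cause, sig in signature.items():
        for i in range(6):
            records.append(
                make_record(
                    f"{cause}{i}", 50.0, "male" if i % 2 else "female",
                    yes=sig, schema=toy_schema, cause=cause,
                )
            )
    return records


@pytest.fixture(scope="session")
def strong_signal_study():
    """One end-to-end run at the default strong-signal study conditions.

    Session-scoped: several tests inspect different facets of the same run.
    """
    from tariffva.evaluation import run_synthetic_study
    from tariffva.simulate import SimulationConfig

    return run_synthetic_study(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
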