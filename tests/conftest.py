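import pandas as pd
import pytest

from screenref import Cohort, GeneratorParams, generate_cohort
from screenref.referral import OperatingConfig


def make_cohort(scores, labels, reader_1=None, reader_2=None, *,
                pi=0.05, split="TEST", **extra) -> Cohort:
    """Small-cohort builder: labels as 'C'/'N', readers as 'R'/'N'."""
    n = len(scores)
    if reader_1 is None:
        reader_1 = ["N"] * n
    if reader_2 is None:
        reader_2 = reader_1
    frame = pd.DataFrame({
        "study_id": [f"id{i}" for i in range(n)],
        "ai_score": scores,
        "label": ["CANCER" if l == "C" else "NORMAL" for l in labels],
        "reader_1": ["RECALL" if r == "R" else "NO_RECALL" for r in reader_1],
        "reader_2": ["RECALL" if r == "R" else "NO_RECALL" for r in reader_2],
        "split": split,
    })
    for key, values in extra.items():
        frame[key] = values
    return Cohort.from_dataframe(frame, pi)


@pytest.fixture
def worked_cohort() -> Cohort:
    """Six-study cohort whose routing can be checked by hand at (0.05, 0.95)."""
    return make_cohort(
        scores=[0.01, 0.99, 0.5, 0.5, 0.02, 0.97],
        labels=["N", "C", "C", "N", "C", "N"],
        reader_1=["R", "N", "R", "N", "R", "N"],
    )


@pytest.fixture
def worked_config() -> OperatingConfig:
    return OperatingConfig(nt_target=0.9, sn_target=0.9,
                           theta_low=0.05, theta_high=0.95)


@pytest.fixture(scope="session")
def medium_cohort():
    """One reusable generated test cohort (enriched, correlated readers)."""
    cohort, truth = generate_cohort(GeneratorParams(n_studies=8000, seed=424242))
    return cohort, truth


@pytest.fixture(scope="session")
def small_val_test():
    """Validation/test cohort pair from the default generator regime."""
    val, _ = generate_cohort(GeneratorParams(
        n_studies=6000, seed=31, split="VALIDATION"))
    test, truth = generate_cohort(GeneratorParams(n_studies=6000, seed=32))
    return val, test, truth
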