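import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from grscore.data_io import GenotypeMatrix, SnpPanel, SubjectTable, psoriasis_panel
from grscore.simulate import calibrate_liability_effects

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> SnpPanel:
    """The packaged ten-SNP psoriasis panel."""
    return psoriasis_panel()


@pytest.fixture(scope="session")
def effects(panel):
    """Calibrated liability effects at 2.5% prevalence (shared; ~2 s once)."""
    return calibrate_liability_effects(panel, 0.025)


@pytest.fixture()
def tiny_panel() -> SnpPanel:
    return SnpPanel(
        pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3"],
                "chrom": ["1", "2", "3"],
                "gene": ["A", "B", "C"],
                "risk_allele": ["T", "G", "A"],
                "nonrisk_allele": ["C", "A", "G"],
                "odds_ratio": [1.59, 2.0, 1.2],
                "case_freq": [0.4, 0.25, 0.6],
                "control_freq": [0.3, 0.2, 0.55],
            }
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def make_genotypes(dosage, snp_ids, subject_ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(
        np.array(subject_ids, object), np.array(snp_ids, object), dosage
    )


def make_subjects(status, **columns) -> SubjectTable:
    n = len(status)
    df = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)], "status": status})
    for name, values in columns.items():
        df[name] = values
    return SubjectTable(df)
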