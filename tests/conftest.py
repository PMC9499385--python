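import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from plasmir.reference import MatureRecord, MiRNAReference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_reference() -> MiRNAReference:
    """Two hand-built hairpins with distinct flanks, so every templated /
    non-templated call is unambiguous by construction."""
    #            0123456789...
    hp_a = "GGGGG" + "ACGTACGTACGTACGTAC" + "TTTTT"  # mature mirA = positions 5..23
    hp_b = "CCCCC" + "TGCATGCATGCATGCATG" + "AAAAA"  # mature mirB = positions 5..23
    matures = [
        MatureRecord(name="mirA", sequence="ACGTACGTACGTACGTAC", hairpin_id="hpA", start=5, end=23),
        MatureRecord(name="mirB", sequence="TGCATGCATGCATGCATG", hairpin_id="hpB", start=5, end=23),
    ]
    return MiRNAReference(matures=matures, hairpins={"hpA": hp_a, "hpB": hp_b})


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort, shared by read-only tests."""
    from plasmir.synthdata import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def random_count_matrix():
    """Small randomized count matrix with metadata, for filter oracles."""
    from plasmir.quantify import CountMatrix

    rng = np.random.default_rng(123)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(50, 20)) * rng.integers(0, 2, size=(50, 20)),
        index=[f"m{i:03d}" for i in range(50)],
        columns=[f"s{j:02d}" for j in range(20)],
    )
    meta = pd.DataFrame(
        {
            "subject_id": [f"p{j % 5}" for j in range(20)],
            "group": [["A", "B", "C", "D"][j % 4] for j in range(20)],
            "percent_mirna_reads": rng.uniform(5, 95, 20),
            "unaligned_pct": rng.uniform(0, 80, 20),
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, samples=meta)
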