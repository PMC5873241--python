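import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dietspec import DietMatrix, PreyRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def rec(
    ind,
    cell="C1",
    fam="Araneidae",
    gen=None,
    guild=None,
    bl=None,
    cw=None,
    unident=False,
    damaged=False,
):
    """Terse PreyRecord constructor for tests."""
    return PreyRecord(
        individual_id=ind,
        cell_id=cell,
        family=fam,
        genus=gen,
        guild=guild,
        body_length_mm=bl,
        carapace_width_mm=cw,
        genus_unidentifiable=unident,
        size_damaged=damaged,
    )


def matrix(counts, level="family", labels=None, individuals=None):
    """Build a DietMatrix from a plain count array."""
    counts = np.asarray(counts, dtype=np.int64)
    n, k = counts.shape
    return DietMatrix(
        individual_ids=tuple(individuals or (f"F{i + 1:02d}" for i in range(n))),
        resource_labels=tuple(labels or (f"R{j + 1}" for j in range(k))),
        counts=counts,
        level=level,
    )


@pytest.fixture
def make_records():
    return rec


@pytest.fixture
def make_matrix():
    return matrix
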