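import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rpqs import GenomeRecord, PqsPattern
from rpqs.synthetic_genome import GCA_CORE, GCA_TAIL, SyntheticSpec, TemplateSpec, generate_synthetic_genome

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pattern() -> PqsPattern:
    return PqsPattern()


def random_genome(seed: int, length: int = 2000, gc: float = 0.5) -> GenomeRecord:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    at = (1 - gc) / 2
    idx = rng.choice(4, size=length, p=[at, gc / 2, gc / 2, at])
    return GenomeRecord(f"rand{seed}", bases[idx].tobytes().decode())


@pytest.fixture(scope="session")
def small_synthetic():
    """Compact scrub-mode genome (60 kb, 12 planted copies) shared by
    tests that only need exact recovery, not the full 500 kb scale."""
    spec = SyntheticSpec(
        length=60_000,
        seed=11,
        templates=[TemplateSpec(core=GCA_CORE, tail=GCA_TAIL, n_copies=12)],
    )
    annotated, truth = generate_synthetic_genome(spec)
    return annotated, truth
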