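import pytest

from mirbs import simulate


@pytest.fixture(scope="session")
def small_bank():
    """Five hairpins with 1-3 CpGs per mature arm; deterministic."""
    hairpins, matures = simulate.generate_reference(
        5, cpgs_per_mature=(1, 3), seed=101
    )
    return hairpins, matures


@pytest.fixture(scope="session")
def medium_bank():
    """Fifty-hairpin bank used for aligner equivalence checks."""
    hairpins, matures = simulate.generate_reference(
        50, cpgs_per_mature=(0, 4), seed=202
    )
    return hairpins, matures
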