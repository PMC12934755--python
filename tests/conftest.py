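import pytest

from rnamotifs import StructureSpec, generate, random_suite, small_suite


@pytest.fixture(scope="session")
def suite200():
    """Planted-recovery suite: 200 seeded structures spanning all classes."""
    return random_suite(200, seed=7)


@pytest.fixture(scope="session")
def suite300():
    return random_suite(300, seed=11)


@pytest.fixture(scope="session")
def suite500():
    return random_suite(500, seed=3)


@pytest.fixture(scope="session")
def small_structures():
    """Compact structures (<= 25 nt) for exhaustive oracle comparisons."""
    suite = small_suite(seed=0)
    assert all(gs.n <= 25 for gs in suite)
    return suite


@pytest.fixture(scope="session")
def pk_canonical():
    """One canonical structure per pseudoknot class."""
    return {
        pk: generate(StructureSpec(motifs=[("PSEUDOKNOT", {"pk_class": pk})], seed=1))
        for pk in ("H", "HHH", "HLOUT", "HLIN", "LL", "LR")
    }
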