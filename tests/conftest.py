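import pytest

from ribopool.synth import PoolSpec, make_hybrid_spec, make_ribotype_family


def trio_specs(seed: int, n_read_pairs: int = 5000, error_rate: float = 0.001,
               amplicon: int = 450):
    """Two 3-ribotype parent species and their 50/50 hybrid.

    Each parent's ribotypes form a family with 2- and 3-step internal
    distances; the two families grow from independent random base
    sequences, so ribotypes of different parents are far more than 5
    steps apart.  Main-ribotype fractions (50/30/20%) sit in the range
    seen in real rDNA pools.
    """
    fam_a = make_ribotype_family(amplicon, 3, [2, 3], seed=seed * 2 + 1, id_prefix="A")
    fam_b = make_ribotype_family(amplicon, 3, [2, 3], seed=seed * 2 + 2, id_prefix="B")
    props = (0.5, 0.3, 0.2)
    parent_a = PoolSpec("parentA", tuple(zip(fam_a, props)),
                        n_read_pairs=n_read_pairs, error_rate=error_rate, seed=seed * 3 + 1)
    parent_b = PoolSpec("parentB", tuple(zip(fam_b, props)),
                        n_read_pairs=n_read_pairs, error_rate=error_rate, seed=seed * 3 + 2)
    hybrid = make_hybrid_spec(parent_a, parent_b, 0.5, "hybrid", seed=seed * 3 + 3)
    return parent_a, parent_b, hybrid


@pytest.fixture
def small_trio():
    """Fast error-free trio for unit tests (800 pairs per pool)."""
    return trio_specs(seed=7, n_read_pairs=800, error_rate=0.0)
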