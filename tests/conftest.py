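import numpy as np
import pytest

import sbscreen as sb


@pytest.fixture(scope="session")
def small_genome():
    """Two random 100 kb chromosomes (fixed seed)."""
    return sb.random_genome({"chr1": 100_000, "chr2": 100_000}, seed=101)


@pytest.fixture(scope="session")
def small_catalog(small_genome):
    cfg = sb.CatalogConfig(
        chrom_lengths={c: len(s) for c, s in small_genome.items()},
        n_genes=6, gene_length=8_000, n_exons=8, seed=102,
    )
    return sb.make_gene_catalog(cfg)


@pytest.fixture(scope="session")
def mouse_catalog():
    """Fifty 10 kb genes on mouse-scale chromosomes (coordinate-only mode)."""
    from sbscreen.simulate import MOUSE_LIKE_CHROMS

    cfg = sb.CatalogConfig(chrom_lengths=MOUSE_LIKE_CHROMS, n_genes=50, seed=103)
    return sb.make_gene_catalog(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
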