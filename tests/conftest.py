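import numpy as np
import pytest

from microscape.genotypes import GenotypeTable
from microscape.surfaces import GridSurface
from microscape.synthetic import mapimi_small, sim_microsat_families


def make_table(genos, loci=None, ids=None, **kw):
    """Build a GenotypeTable from a nested list [[(a,b), ...], ...]."""
    calls = np.array(genos, dtype=int)
    n, L = calls.shape[0], calls.shape[1]
    ids = ids or [f"i{k}" for k in range(n)]
    loci = loci or [f"L{k}" for k in range(L)]
    return GenotypeTable(ids, loci, calls, **kw)


@pytest.fixture(scope="session")
def family_panel():
    """8-locus, 10-allele panel with designed U/HS/FS/PO dyads."""
    return sim_microsat_families(
        n_loci=8, n_alleles=10, n_unrelated=20, n_po=3, n_fs=3, n_hs=3, seed=11
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A small synthetic study (16x16 raster, 25 individuals)."""
    return mapimi_small(
        seed=7, n_rows=16, n_cols=16, n_individuals=25, correlation_length=20.0
    ).generate()


@pytest.fixture()
def ramp_surface():
    """Linear left-to-right ramp, 10x20 grid of 5 m cells."""
    vals = np.tile(np.linspace(0.0, 1.0, 20), (10, 1))
    return GridSurface(vals, cell_size=5.0)
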