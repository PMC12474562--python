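import numpy as np
import pandas as pd
import pytest

from salrun import sim
from salrun.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale 3-region simulation used by several module tests."""
    return sim.SimConfig(
        n_pops=6,
        pops_per_region=(2, 2, 2),
        n_ind_per_pop=20,
        n_snps=400,
        latitudes=(46.0, 47.0, 49.0, 50.0, 53.0, 55.0),
        n_trait_loci=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    g, truth = sim.simulate_genotypes(small_cfg)
    counts = sim.simulate_counts(small_cfg, truth.modality_labels)
    pheno = sim.population_phenotypes(small_cfg, counts, truth)
    return {"cfg": small_cfg, "g": g, "truth": truth, "counts": counts, "pheno": pheno}


def toy_genotypes(dosages, pops=None, chrom=None, pos=None):
    """GenotypeMatrix from a plain dosage array (individuals x SNPs)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else list(range(100, 100 + 10 * m, 10)),
            "ref": "A",
            "alt": "T",
        }
    )
    inds = [f"i{i}" for i in range(n)]
    pops = pops if pops is not None else ["P1"] * n
    return GenotypeMatrix(dosages, markers, inds, list(pops))


@pytest.fixture
def counts_table():
    """Helper building long-form count tables from {doy: count} dicts."""

    def build(per_day, population="P", year=2000, size_class="combined"):
        rows = [
            (population, year, doy, size_class, c) for doy, c in sorted(per_day.items())
        ]
        return pd.DataFrame(rows, columns=["population", "year", "doy", "size_class", "count"])

    return build
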