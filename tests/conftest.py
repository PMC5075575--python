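import numpy as np
import pandas as pd
import pytest

from magicqtl.gmap import GeneticMap, demo_map
from magicqtl.hmm import FounderHMM
from magicqtl.pheno import average_replicates
from magicqtl.phenosim import simulate_phenotypes
from magicqtl.presets import qtl_spec
from magicqtl.simulate import (
    FounderSet,
    emit_genotypes,
    simulate_founders,
    simulate_population_mosaics,
)


def make_map(chrom_lengths: dict[str, float], n: int = 11) -> GeneticMap:
    """Evenly spaced test map with the given chromosome lengths (cM)."""
    parts = []
    for chrom, length in chrom_lengths.items():
        parts.append(pd.DataFrame({
            "marker": [f"{chrom}_m{i}" for i in range(n)],
            "chrom": chrom,
            "cM": np.linspace(0.0, length, n),
        }))
    return GeneticMap(pd.concat(parts, ignore_index=True))


@pytest.fixture(scope="session")
def tiny_map() -> GeneticMap:
    return make_map({"1A": 50.0, "2B": 80.0}, n=11)


@pytest.fixture(scope="session")
def small_founders(tiny_map) -> FounderSet:
    return simulate_founders(tiny_map, 8, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_population(small_founders, tiny_map):
    """60 RILs with genotypes, used by several structural tests."""
    mosaics, ids = simulate_population_mosaics(
        small_founders, tiny_map, n_lines=60, seed=12
    )
    geno = emit_genotypes(mosaics, small_founders, 0.005, 0.02, seed=13,
                          line_ids=ids)
    return mosaics, ids, geno


@pytest.fixture(scope="session")
def planted_dataset():
    """One 208-line population on the desk map with two planted QTLs.

    Returns (founders, mosaics, genotypes, founder probabilities,
    line-mean phenotype table) for reuse across scan-level tests.
    """
    gmap = demo_map(100)
    founders = simulate_founders(gmap, 8, 0.5, seed=101)
    mosaics, ids = simulate_population_mosaics(founders, gmap, 208, seed=102)
    geno = emit_genotypes(mosaics, founders, 0.005, 0.0219, seed=103,
                          line_ids=ids)
    qtls = [qtl_spec("GS39", "BS00009369_51"), qtl_spec("SH", "RAC875_c1673_193")]
    pheno = simulate_phenotypes(mosaics, founders, qtls, seed=104, line_ids=ids)
    F = FounderHMM().fit(founders).transform(geno)
    means = average_replicates(pheno).set_index("line_id")
    return founders, mosaics, geno, F, means
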