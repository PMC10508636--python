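import numpy as np
import pandas as pd
import pytest

from ascbias.genotypes import GenotypeMatrix, mutation_class


def make_gm(calls, populations, chrom=None, pos=None, anc=None, der=None):
    """Small genotype matrix from a (sites x individuals) nested list.

    ``populations`` assigns one population label per individual; individual
    ids are "<pop>_<k>".
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_ind = calls.shape
    if chrom is None:
        chrom = ["1"] * n_sites
    if pos is None:
        pos = list(range(1, n_sites + 1))
    if anc is None:
        anc = ["A"] * n_sites
    if der is None:
        der = ["G"] * n_sites
    counters = {}
    ids = []
    for p in populations:
        counters[p] = counters.get(p, 0) + 1
        ids.append(f"{p}_{counters[p]}")
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "anc": anc, "der": der,
        "mclass": [mutation_class(a, d) for a, d in zip(anc, der)],
    })
    return GenotypeMatrix(
        sites=sites,
        individuals=pd.DataFrame({"id": ids, "population": list(populations)}),
        calls=calls,
    )


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same stream regardless of which
    # other tests run, keeping outcomes deterministic under test selection
    return np.random.default_rng(20240917)
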