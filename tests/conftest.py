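import numpy as np
import pandas as pd
import pytest

from sweepscan import GenotypeMatrix, PopulationMap, SimConfig, filter_sites, simulate


def make_matrix(calls, positions=None, contig="chr1", contig_length=None):
    """GenotypeMatrix from a samples x sites dosage array (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {"contig": contig, "pos": positions, "ref": "A", "alt": "G"}
    )
    length = contig_length or int(max(positions)) + 100
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        sites=sites,
        calls=calls,
        contig_lengths={contig: length},
    )


def split_popmap(G, n_first, name_a="A", name_b="B"):
    """Assign the first n_first samples to one population, the rest to another."""
    return PopulationMap(
        {
            s: (name_a if i < n_first else name_b)
            for i, s in enumerate(G.sample_ids)
        }
    )


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted-sweep fixture: simulate, filter, keep truth."""
    G, popmap, genes, truth = simulate(SimConfig())
    full_lengths = dict(G.contig_lengths)
    G_filtered, counts = filter_sites(G)
    return {
        "raw": G,
        "filtered": G_filtered,
        "popmap": popmap,
        "genes": genes,
        "truth": truth,
        "filter_counts": counts,
        "contig_lengths": full_lengths,
    }
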