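import pandas as pd
import pytest

import pollenpipe as pp


@pytest.fixture(scope="session")
def genome():
    """A small two-chromosome genome with genes and TE families."""
    return pp.simulate_genome(seed=11, n_chrom=2, chrom_length=20_000, n_genes=6, n_tes=12)


@pytest.fixture(scope="session")
def planted_truth(genome):
    """Methylation truth with CHH-hypomethylated islands on the first TEs."""
    tes = genome.features_of_class("TE")
    regions = [
        pp.PlantedRegion(te, "CHH", delta=-0.3, ref_level=0.4) for te in tes[:4]
    ]
    return pp.MethylationTruth(planted_regions=regions, coverage_mean=20.0)


def cytosine_table(rows):
    """Helper: build a cytosine table from (chrom, pos, strand, context,
    meth, unmeth) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"]
    )


@pytest.fixture
def make_cytosine_table():
    return cytosine_table
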