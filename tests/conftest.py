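"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pandas as pd
import pytest

from methdiverge import synthetic
from methdiverge.methio import MethylomeSample


@pytest.fixture(scope="session")
def small_design():
    """2 species x 1 tissue x 2 replicates on 400 kb with 20 planted DMRs."""
    return synthetic.SimulationDesign(
        seed=1,
        n_contigs=2,
        contig_length=200_000,
        n_species=2,
        n_tissues=1,
        n_replicates=2,
        n_dmrs=20,
        n_genes=15,
        n_tes=60,
        n_cgis=10,
        species_effect=0.0,
    )


@pytest.fixture(scope="session")
def small_refset(small_design):
    return synthetic.generate_reference_set(small_design)


@pytest.fixture(scope="session")
def small_methylomes(small_design, small_refset):
    return synthetic.simulate_methylomes(small_design, small_refset, build_reports=True)


@pytest.fixture(scope="session")
def small_samples(small_methylomes):
    return [sm.to_sample() for sm in small_methylomes]


@pytest.fixture(scope="session")
def small_groups(small_samples):
    a = [s for s in small_samples if s.species == "sp01"]
    b = [s for s in small_samples if s.species == "sp02"]
    return a, b


def make_sample(rows, sample_id="s", species="sp", tissue="liver", replicate=1):
    """Build a MethylomeSample from (contig, position, meth, unmeth) rows."""
    sites = pd.DataFrame(rows, columns=["contig", "position", "count_methylated", "count_unmethylated"])
    return MethylomeSample(sample_id, species, tissue, replicate, sites)


def uniform_group(positions, meth, cov, n_reps=2, species="sp", start_rep=1):
    """Replicated samples with identical counts at the given positions."""
    return [
        make_sample(
            [("chr1", int(p), int(m), int(c - m)) for p, m, c in zip(positions, meth, cov)],
            sample_id=f"{species}_r{start_rep + i}",
            species=species,
            replicate=start_rep + i,
        )
        for i in range(n_reps)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
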