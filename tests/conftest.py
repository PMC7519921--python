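import numpy as np
import pandas as pd
import pytest

from pygmyscan import (
    GenotypeMatrix,
    PopulationManifest,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30+30-sample, 300-locus cohort with 10 planted loci at (0.9, 0.1)."""
    cfg = SimulationConfig(
        n_pop1=30,
        n_pop2=30,
        n_variants=300,
        fst_background=0.05,
        n_planted=10,
        planted_freqs=(0.9, 0.1),
        missing_rate=0.02,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def two_pop_manifest():
    """Four-sample manifest: two samples per population."""
    return PopulationManifest(
        pd.DataFrame(
            {"population": ["p1", "p1", "p2", "p2"], "sex": ["M", "F", "M", "F"]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )


def make_matrix(dosages, samples, ids=None, chrom="1"):
    """Build a GenotypeMatrix from a plain nested list of dosages."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[0]
    ids = ids if ids is not None else [f"v{i}" for i in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 10,
            "id": ids,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(dosages, variants, list(samples))
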