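import numpy as np
import pytest

from clusterforge.synthetic import (ClusterSpec, GenomeRecipe, MiteSpec,
                                    TeFamilySpec, TelomereSpec,
                                    generate_genome)


@pytest.fixture(scope="session")
def small_genome():
    """300 kb single-contig genome with repeats, MITEs, telomeres, cluster."""
    recipe = GenomeRecipe(
        seed=101,
        contigs=(("chr1", 300_000),),
        te_families=(TeFamilySpec("tahi", 2500, 6, sub_rate=0.03),
                     TeFamilySpec("waru", 1200, 4, sub_rate=0.05, rip_rate=0.4)),
        mites=(MiteSpec("m8", length=260, tir_len=28, copies=5),),
        telomeres=TelomereSpec(ends=(("chr1", "right"), ("chr1", "left"))),
        clusters=(ClusterSpec("eas_like", "chr1", telomere_distance=15_000),),
    )
    return generate_genome(recipe)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
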