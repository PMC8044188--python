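import numpy as np
import pandas as pd
import pytest

from heteropop.genotype_io import GenotypeMatrix, VariantTable
from heteropop.simpop import SimConfig, simulate_panel


def make_variants(positions, chromosome="1", ref="A", alt="C"):
    rows = [(f"S{chromosome}_{p}", chromosome, p, ref, alt)
            for p in positions]
    return VariantTable(pd.DataFrame(
        rows, columns=["locus_id", "chromosome", "position_bp",
                       "ref_allele", "alt_allele"]))


@pytest.fixture
def small_panel():
    """60 lines x 300 loci, 3 well-separated groups, mostly pure lines."""
    cfg = SimConfig(n_lines=60, n_loci=300, n_chromosomes=2,
                    K_true=3, divergence_F=(0.3,), pure_fraction=1.0,
                    residual_het_rate=0.02, missing_rate=0.05, seed=11)
    return simulate_panel(cfg)


@pytest.fixture
def toy_matrix():
    """5 lines x 4 loci with a het and a missing call."""
    v = np.array([
        [0, 2, 1, 0],
        [2, 0, 0, 0],
        [0, 2, 2, 0],
        [2, 0, 0, -1],
        [0, 2, 2, 0],
    ], dtype=np.int8)
    return GenotypeMatrix(v, [f"l{i}" for i in range(5)],
                          [f"s{j}" for j in range(4)])
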