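import numpy as np
import pandas as pd
import pytest

from histgp.genomics import MarkerMatrix
from histgp.simdata import FieldDesign, SimConfig, simulate_breeding_program, simulate_study


def tiny_field(**kw):
    """Small alpha-lattice: 10-entry subtrials (2 checks), 2 reps, 2x5 blocks."""
    defaults = dict(genotypes_per_subtrial=10, n_checks_per_subtrial=2,
                    n_reps=2, blocks_per_rep=2, plots_per_block=5)
    defaults.update(kw)
    return FieldDesign(**defaults)


def tiny_config(**kw):
    defaults = dict(n_years=3, lines_per_year=24, n_markers=120,
                    n_chromosomes=4, n_qtl=40, n_checks=2,
                    n_parents_per_cohort=12, field=tiny_field(), seed=7)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_program():
    cfg = tiny_config()
    markers, truth = simulate_breeding_program(cfg)
    return cfg, markers, truth


@pytest.fixture(scope="session")
def tiny_study():
    cfg = tiny_config()
    return cfg, *simulate_study(cfg)


def random_marker_matrix(rng, n, m, years=None):
    p = rng.uniform(0.1, 0.5, m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    ids = np.array([f"I{i:04d}" for i in range(n)], dtype=object)
    markers = pd.DataFrame({"chrom": 1, "pos": np.arange(1, m + 1)},
                           index=[f"M{j:04d}" for j in range(m)])
    return MarkerMatrix(ids=ids, dosage=dosage, markers=markers, years=years)
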