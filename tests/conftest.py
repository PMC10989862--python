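import numpy as np
import pandas as pd
import pytest

from vinegp import simcross as sc
from vinegp.genomat import GenotypeMatrix


def stack_crosses(founders, cross_specs, seed0=100):
    """GenotypeMatrix of several full-sib families from one founder set."""
    mats = [
        sc.simulate_cross(founders, a, b, n, seed=seed0 + i, id_prefix=f"C{i + 1}")
        for i, (a, b, n) in enumerate(cross_specs)
    ]
    return GenotypeMatrix(
        np.vstack([m.dosages for m in mats]),
        founders.markers.copy(),
        pd.concat([m.individuals for m in mats]),
    )


@pytest.fixture(scope="session")
def founders():
    cfg = sc.SimConfig(
        n_founders=6, n_chromosomes=3, snps_per_chromosome=60,
        map_length_cM=100.0, seed=7,
    )
    return sc.simulate_founders(cfg)


@pytest.fixture(scope="session")
def multi_cross(founders):
    """Eight crosses sharing parents, 50 offspring each (training-set-like)."""
    specs = [
        ("P1", "P4", 50), ("P1", "P5", 50), ("P2", "P4", 50), ("P2", "P5", 50),
        ("P3", "P6", 50), ("P3", "P4", 50), ("P1", "P6", 50), ("P2", "P6", 50),
    ]
    return stack_crosses(founders, specs)


@pytest.fixture(scope="session")
def small_program():
    """A compact breeding program with two sets, controls, missingness and a
    major-gene binary trait."""
    cfg = sc.SimConfig(
        n_founders=6, n_chromosomes=5, snps_per_chromosome=60, seed=11
    )
    crosses = [
        {"parent_a": "P1", "parent_b": "P4", "n_ts": 35, "n_vs": 15},
        {"parent_a": "P1", "parent_b": "P5", "n_ts": 35, "n_vs": 15},
        {"parent_a": "P2", "parent_b": "P4", "n_ts": 35, "n_vs": 15},
        {"parent_a": "P2", "parent_b": "P6", "n_ts": 35, "n_vs": 15},
    ]
    traits = [
        sc.TraitArchitecture(
            name="acidity", n_qtl=120, target_h2=0.6, cross_variance_fraction=0.3,
            spatial_row_var=0.1, spatial_col_var=0.1, year_var=0.3,
        ),
        sc.TraitArchitecture(
            name="berry_weight", n_qtl=20, target_h2=0.4,
            cross_variance_fraction=0.2, year_var=0.2,
        ),
        sc.TraitArchitecture(
            name="sugar", n_qtl=80, target_h2=0.3, cross_variance_fraction=0.2,
        ),
    ]
    return sc.simulate_program(
        cfg, crosses, traits, years=[2018, 2019], grid_rows=15, grid_cols=10,
        control_parents=["P1", "P2"], control_reps=5,
        missing_rate=0.03, binary_penetrance=0.95, seed=11,
    )
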