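"""Shared fixtures: small pedigrees and seeded mixed-model systems."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import connekt as ck


@pytest.fixture
def trio_pedigree() -> ck.PedigreeTable:
    """Two founders and their offspring."""
    return ck.PedigreeTable([("1", None, None), ("2", None, None), ("3", "1", "2")])


@pytest.fixture
def fullsib_pedigree() -> ck.PedigreeTable:
    """Founders 1,2; full sibs 3,4; inbred offspring 5 = 3 x 4."""
    return ck.PedigreeTable(
        [
            ("1", None, None),
            ("2", None, None),
            ("3", "1", "2"),
            ("4", "1", "2"),
            ("5", "3", "4"),
        ]
    )


def make_system(
    seed: int,
    n_founders: int = 12,
    generations: int = 3,
    offspring: int = 24,
    n_units: int = 3,
    h2: float = 0.5,
    with_sex: bool = False,
):
    """Seeded pedigree-based mixed-model system for identity checks.

    Returns (system, pev_store, A, varcomp).  All individuals are phenotyped;
    the unit assignment comes from k-medoids on the numerator relationship
    matrix, so units reflect genuine family structure.
    """
    cfg = ck.SimConfig(
        n_founders=n_founders,
        generations=generations,
        offspring_per_generation=offspring,
        n_units=n_units,
        h2=h2,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    ped = ck.simulate_pedigree(cfg, rng)
    A = ck.build_A(ped)
    units = ck.assign_units(A, n_units, rng)
    pheno_df = ck.simulate_phenotypes(A, cfg, units, rng)
    pt = ck.PhenotypeTable(pheno_df[["id", "sex", "unit", "phenotype"]])
    varcomp = ck.VarianceComponents.from_h2(h2)
    Kinv, _ = ck.regularize_and_invert(A)
    fixed = ["sex"] if with_sex else []
    design = ck.build_design(pt, A.individual_ids, fixed)
    system = ck.build_mme(design, Kinv, varcomp)
    return system, ck.pev(system), A, varcomp


@pytest.fixture
def unit_only_system():
    return make_system(seed=11)


@pytest.fixture
def unit_sex_system():
    return make_system(seed=11, with_sex=True)


@pytest.fixture
def toy_phenotypes() -> ck.PhenotypeTable:
    """Four records, two units, balanced sex."""
    return ck.PhenotypeTable(
        pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "unit": ["u1", "u1", "u2", "u2"],
                "sex": ["M", "F", "M", "F"],
                "phenotype": [1.0, 2.0, 3.0, 4.0],
            }
        )
    )
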