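"""Shared fixtures: one seeded medium-scale cross reused across the suite.

The medium simulation is the recovery benchmark: 2 chromosomes of 5 Mb
with 2,000 markers each, a 7x7 cross totalling 200 progeny, 1% genotype
error and 5% missingness, generator defaults otherwise (1.2 COs per
chromosome per gamete, 1.2x male multiplier on every other chromosome,
gamma-renewal interference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from gametemap import codetect, pedigree as ped_mod, phasing, simcross
from gametemap.containers import GenomeLayout

MEDIUM_SEED = 1


@pytest.fixture(scope="session")
def layout() -> GenomeLayout:
    return GenomeLayout.test_scale(2, 5_000_000)


@pytest.fixture(scope="session")
def medium_sim(layout):
    landscape = simcross.RecombLandscape.uniform(layout)
    parents = simcross.simulate_parent_haplotypes(layout, 2000, seed=MEDIUM_SEED)
    geno, ped, truth = simcross.simulate_factorial_cross(
        parents,
        landscape,
        simcross.default_family_sizes(200),
        error_rate=0.01,
        missing_rate=0.05,
        seed=MEDIUM_SEED,
    )
    return {"layout": layout, "landscape": landscape, "parents": parents,
            "geno": geno, "ped": ped, "truth": truth}


@dataclass
class ParentAnalysis:
    corrected: np.ndarray
    contrib: object
    haps: object
    conflicts: pd.DataFrame
    co: pd.DataFrame
    blocks: pd.DataFrame
    smoothed: dict


@pytest.fixture(scope="session")
def medium_analysis(medium_sim) -> dict[str, ParentAnalysis]:
    """QC + phasing + CO detection for every parent of the medium cross."""
    geno, ped = medium_sim["geno"], medium_sim["ped"]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for parent in ped.parents:
            dosage, _ = ped_mod.correct_parental_genotypes(geno, ped, parent)
            haps, contrib, conflicts = phasing.phase_parent(geno, ped, parent, dosage)
            co, blocks, smoothed = codetect.detect_crossovers(
                contrib, haps, ped.sex_of(parent)
            )
            out[parent] = ParentAnalysis(dosage, contrib, haps, conflicts, co, blocks, smoothed)
    return out


@pytest.fixture(scope="session")
def medium_co(medium_analysis) -> pd.DataFrame:
    return pd.concat([a.co for a in medium_analysis.values()], ignore_index=True)


@pytest.fixture(scope="session")
def medium_blocks(medium_analysis) -> pd.DataFrame:
    return pd.concat([a.blocks for a in medium_analysis.values()], ignore_index=True)


@pytest.fixture(scope="session")
def errorfree_sim(layout):
    """Small error-free cross for exactness tests (500 markers, 98 progeny)."""
    landscape = simcross.RecombLandscape.uniform(layout)
    parents = simcross.simulate_parent_haplotypes(layout, 500, seed=3)
    geno, ped, truth = simcross.simulate_factorial_cross(
        parents, landscape, simcross.default_family_sizes(98),
        error_rate=0.0, missing_rate=0.0, seed=3,
    )
    return {"layout": layout, "landscape": landscape, "parents": parents,
            "geno": geno, "ped": ped, "truth": truth}
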