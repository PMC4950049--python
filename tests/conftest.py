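import numpy as np
import pandas as pd
import pytest

import autozyg as az


@pytest.fixture(scope="session")
def fullsib_pedigree() -> az.Pedigree:
    """A and B are founders; C, D their full-sib offspring; E = C x D."""
    return az.Pedigree.from_records(
        [("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B"),
         ("D", "A", "B"), ("E", "C", "D")]
    )


@pytest.fixture(scope="session")
def small_cfg() -> az.SimulationConfig:
    """Desk-scale study conditions for fast tests (fewer cohorts/markers)."""
    return az.SimulationConfig(
        n_cohorts=6,
        n_founder_females=25,
        n_founder_males=12,
        offspring_per_cohort=60,
        n_chromosomes=8,
        n_snps=800,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """One simulated population shared by read-only tests."""
    ped = az.simulate_pedigree(small_cfg, seed=11)
    gm, mmap, truth = az.gene_drop(ped, small_cfg, seed=12)
    return ped, gm, mmap, truth


def make_genotype_matrix(dosages, ids=None, markers=None) -> az.GenotypeMatrix:
    d = np.asarray(dosages, dtype=np.int8)
    return az.GenotypeMatrix(
        ids=ids or [f"i{k}" for k in range(d.shape[0])],
        markers=markers or [f"m{j}" for j in range(d.shape[1])],
        dosages=d,
    )


def make_map(bp_by_chrom: dict, genome_length_kb: float | None = None) -> az.MarkerMap:
    rows = []
    for chrom, positions in bp_by_chrom.items():
        for b in positions:
            rows.append((f"s{chrom}_{b}", str(chrom), int(b), b / 1e6))
    table = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cm"])
    kw = {} if genome_length_kb is None else {"genome_length_kb": genome_length_kb}
    return az.MarkerMap(table, **kw)
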