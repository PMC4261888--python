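"""Shared fixtures: the default 8-population scenario and small helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ldphase as lp


@pytest.fixture(scope="session")
def scenario():
    """One realisation of the default 8-population study design.

    Returns (genotypes dict, marker map, seed log); simulated once per
    session and shared by integration tests.
    """
    return lp.simulate_scenario(lp.default_scenario(seed=2014))


@pytest.fixture(scope="session")
def qc_scenario(scenario):
    """QC-filtered matrices and reports for the default scenario."""
    genotypes, marker_map, _ = scenario
    filtered, reports = {}, {}
    for name, g in genotypes.items():
        filtered[name], reports[name] = lp.run_qc(g, marker_map)
    return filtered, reports, marker_map


@pytest.fixture(scope="session")
def pair_tables(qc_scenario):
    """Pair-LD tables for every population on the all-population
    marker intersection."""
    filtered, _, marker_map = qc_scenario
    common = lp.intersect_markers(list(filtered.values()))
    return {g.population: lp.pair_ld_table(g, marker_map) for g in common}


def make_genotypes(codes, population="pop", snp_ids=None):
    """GenotypeMatrix from a plain nested list (rows = samples)."""
    codes = np.asarray(codes, dtype=np.int8)
    snps = snp_ids or [f"s{i}" for i in range(codes.shape[1])]
    samples = [f"ind{i}" for i in range(codes.shape[0])]
    return lp.GenotypeMatrix(population, samples, np.asarray(snps), codes)


def make_map(snp_ids, chroms, pos_bp):
    return lp.MarkerMap(
        pd.DataFrame({"snp_id": snp_ids, "chrom": [str(c) for c in chroms], "pos": pos_bp})
    )


@pytest.fixture
def toy_map():
    return make_map([f"s{i}" for i in range(4)], ["1"] * 4, [1000, 51000, 101000, 301000])
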