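"""Shared fixtures: replicate banks of scaled simulations.

All heavy simulation work lives in session-scoped banks so the
acceptance tests that share study conditions (heritability recovery,
twin studies, association power) reuse the same replicates.  Scale
0.05 (N = 1000, 8N-generation burn-in) keeps per-gamete rates at their
full-scale values, preserving house-of-cards expectations.
"""

from __future__ import annotations

import numpy as np
import pytest

from regionsim.core import DemographyEpoch, SimulationConfig, standard_config
from regionsim.simulate import run_simulation
from regionsim.traits import TraitModelSpec

SCALE = 0.05


def make_bank(model, sigma_e, lambda_, n_reps, seed0, scenario="no_growth", h=1.0):
    bank = []
    for s in range(n_reps):
        cfg = standard_config(
            scenario, lambda_, sigma_e, model=model, h=h, scale=SCALE, seed=seed0 + s
        )
        pop, ts = run_simulation(cfg)
        bank.append((pop, ts, cfg))
    return bank


@pytest.fixture(scope="session")
def ac_bank():
    """20 AC replicates, lambda=0.5, sigma_e=0.075 (the H2~0.08 condition)."""
    return make_bank("AC", 0.075, 0.5, 20, 11000)


@pytest.fixture(scope="session")
def ac_wide_bank():
    """20 AC replicates with sigma_e=0.11 (the H2~0.04 condition)."""
    return make_bank("AC", 0.11, 0.5, 20, 12000)


@pytest.fixture(scope="session")
def gbr_bank():
    """20 GBR replicates, lambda=0.5, sigma_e=0.053 (the H2~0.08 condition)."""
    return make_bank("GBR", 0.053, 0.5, 20, 13000)


@pytest.fixture(scope="session")
def gbr_twin_bank(gbr_bank):
    """100 GBR replicates for twin studies (gbr_bank plus 80 more)."""
    return gbr_bank + make_bank("GBR", 0.053, 0.5, 80, 14000)


N_ASSOC_REPS = 100
N_CASE = N_CONTROL = 150
N_PERM = 2000


@pytest.fixture(scope="session")
def assoc_results():
    """Streaming association study over three lambda=0.125 conditions.

    Populations are processed one at a time (growth-scenario final
    populations are large) into per-replicate summaries: minimum
    single-marker p-values under both study designs, region-test
    results (GBR constant-N arm), and the singleton fraction of a
    100-diploid sample.
    """
    from regionsim.association import (
        ascertain_case_control,
        make_chip,
        single_marker_logistic,
    )
    from regionsim.regiontests import region_test
    from regionsim.varcomp import sample_from_population

    conditions = (
        ("ac_ng", "AC", 0.075, "no_growth", 21000),
        ("gbr_ng", "GBR", 0.053, "no_growth", 22000),
        ("gbr_growth", "GBR", 0.053, "growth", 23000),
    )
    out = {}
    for name, model, sigma_e, scenario, seed0 in conditions:
        res = {"chip_minp": [], "reseq_minp": [], "esm": [], "skat_beta": [],
               "singleton_frac": []}
        for i in range(N_ASSOC_REPS):
            cfg = standard_config(
                scenario, 0.125, sigma_e, model=model, scale=SCALE, seed=seed0 + i
            )
            pop, _ = run_simulation(cfg)
            rng = np.random.default_rng(90_000 + i)
            idx = rng.choice(pop.n_diploids, 100, replace=False)
            ac = pop.dosages()[idx].sum(axis=0)
            poly = ac[(ac > 0) & (ac < 200)]
            if poly.size:
                res["singleton_frac"].append(float(np.mean(poly == 1)))
            sm = sample_from_population(
                pop, cfg.trait_model, rng, n=min(1000, pop.n_diploids), sites="all"
            )
            panel = ascertain_case_control(sm, N_CASE, N_CONTROL, rng=rng)
            for design, key in (("gene_chip", "chip_minp"), ("resequencing", "reseq_minp")):
                sites = np.nonzero(make_chip(panel, design))[0]
                if sites.size == 0:
                    res[key].append(1.0)
                    continue
                pv, _ = single_marker_logistic(panel, sites=sites)
                res[key].append(float(pv.min()))
            if name == "gbr_ng":
                res["esm"].append(
                    region_test(panel, "esm", max_permutations=N_PERM,
                                rng=np.random.default_rng(95_000 + i))
                )
                res["skat_beta"].append(
                    region_test(panel, "skat_beta", max_permutations=N_PERM,
                                rng=np.random.default_rng(95_000 + i))
                )
        out[name] = res
    return out


@pytest.fixture(scope="session")
def mr_pop():
    """An incomplete-MR (h=0.25) population at the H2~0.08 condition.

    Seeds are scanned in order until a replicate with segregating
    causal variation is found (the decomposition identity is vacuous
    on a causal-monomorphic population).
    """
    from regionsim.traits import genetic_values_matrix

    for seed in range(31000, 31050):
        cfg = standard_config(
            "no_growth", 0.5, 0.068, model="MR", h=0.25, scale=SCALE, seed=seed
        )
        pop, _ = run_simulation(cfg)
        g = genetic_values_matrix(pop.occupancy, pop.mutations.effects, cfg.trait_model)
        if g.var() > 0:
            return pop, cfg
    raise RuntimeError("no MR replicate with causal variation in 50 seeds")


@pytest.fixture(scope="session")
def tiny_pop():
    """A fast small population for structural/IO tests."""
    cfg = SimulationConfig(
        demography=[DemographyEpoch(duration=400, start_size=120, end_size=120)],
        trait_model=TraitModelSpec(model="AC", lambda_=0.25, sigma_e=0.075),
        seed=777,
    )
    pop, ts = run_simulation(cfg)
    return pop, ts, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
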