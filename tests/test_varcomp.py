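"""Variance partitioning, GRMs, HE regression, load and SFS summaries."""

import numpy as np
import pytest
from scipy import stats

from regionsim.io import fixture_unlinked_markers
from regionsim.varcomp import (
    SampleMatrix,
    burden_ratio,
    dominance_code,
    fisher_site_variance,
    gamete_summaries,
    genetic_load,
    grm_additive,
    grm_dominance,
    he_regression,
    sample_from_population,
    sfs,
    variance_curve,
)


def hwe_sample(rng, n, q, alpha):
    """Unlinked HWE genotypes with an additive trait."""
    q = np.asarray(q)
    alpha = np.asarray(alpha)
    dos = rng.binomial(2, q, size=(n, len(q))).astype(np.int8)
    g = dos @ alpha
    return SampleMatrix(
        dosages=dos,
        site_freq=q,
        site_effect=alpha,
        phenotypes=g,
        genetic_values=g,
    )


class TestDominanceCode:
    @pytest.mark.parametrize(
        "dosage,q,expected", [(0, 0.3, 0.0), (1, 0.5, 1.0), (2, 0.5, 0.0), (2, 0.3, -0.8)]
    )
    def test_coding_values(self, dosage, q, expected):
        assert dominance_code(dosage, q) == pytest.approx(expected)

    @pytest.mark.parametrize("q", [0.01, 0.1, 0.5, 0.9])
    def test_orthogonal_to_additive_under_hwe(self, q):
        # enumerate the three genotype classes at HWE proportions
        dosages = np.array([0, 1, 2])
        probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        add = dosages.astype(float)
        dom = dominance_code(dosages, q)
        cov = probs @ (add * dom) - (probs @ add) * (probs @ dom)
        assert cov == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dominance_code(3, 0.5)
        with pytest.raises(ValueError):
            dominance_code(1, 0.0)


class TestVarianceCurve:
    def test_additive_population_fully_explained(self, ac_bank, rng):
        checked = 0
        for pop, _, cfg in ac_bank:
            sm = sample_from_population(pop, cfg.trait_model, rng, sites="causal")
            if sm.genetic_values.var() == 0:
                continue  # no segregating causal variation: identity vacuous
            vc = variance_curve(sm, [1.0])
            assert vc.va_cum[-1] == pytest.approx(1.0, abs=1e-6)
            checked += 1
        assert checked > 0

    def test_single_site_any_threshold_above_q(self, rng):
        sm = hwe_sample(rng, 500, [0.2], [0.7])
        vc = variance_curve(sm, [0.1, 0.3, 1.0])
        assert vc.va_cum[0] == 0.0  # threshold below q selects nothing
        assert vc.va_cum[1] == pytest.approx(1.0, abs=1e-9)
        assert vc.va_cum[2] == pytest.approx(1.0, abs=1e-9)

    def test_curves_monotone_and_ordered(self, gbr_bank, rng):
        sm = next(
            s
            for pop, _, cfg in gbr_bank
            if (s := sample_from_population(pop, cfg.trait_model, rng, sites="causal"))
            .genetic_values.var()
            > 0
        )
        thr = [0.001, 0.01, 0.05, 0.25, 1.0]
        vc = variance_curve(sm, thr)
        eps = 1e-8
        assert np.all(np.diff(vc.va_cum) >= -0.02)  # up to estimation noise
        assert np.all(vc.vad_cum >= vc.va_cum - eps)
        assert np.all(vc.vad_cum <= 1.0 + eps)

    def test_gbr_epistasis_leaves_variance_unexplained(self, gbr_bank, rng):
        # compound-heterozygote (cis) effects are neither additive nor
        # per-site dominance: the joint fit stays short of unity
        vals = []
        for pop, _, cfg in gbr_bank:
            sm = sample_from_population(pop, cfg.trait_model, rng, sites="causal")
            if sm.genetic_values.var() == 0:
                continue
            vc = variance_curve(sm, [1.0])
            vals.append(vc.vad_cum[-1])
        assert len(vals) >= 10
        assert np.mean(vals) < 0.95


class TestFisherVariance:
    @pytest.mark.parametrize(
        "q,a,expected", [(0.5, 1.0, 0.5), (0.1, 0.1, 0.0018)]
    )
    def test_formula(self, q, a, expected):
        assert fisher_site_variance(q, a) == pytest.approx(expected)

    def test_regression_matches_classical_formula(self, rng):
        # per-marker variance from the joint regression of genetic value
        # on all markers vs 2 p q alpha^2, on unlinked HWE markers
        # (neutral WF frequency density, exponential effects)
        sm = fixture_unlinked_markers(400, 3000, lambda_=0.1, rng=rng)
        x = sm.dosages.astype(float)
        design = np.column_stack([np.ones(len(x)), x])
        coef, _, _, _ = np.linalg.lstsq(design, sm.genetic_values, rcond=None)
        reg = coef[1:] ** 2 * x.var(axis=0)
        fisher = fisher_site_variance(sm.site_freq, sm.site_effect)
        assert np.corrcoef(reg, fisher)[0, 1] > 0.99


class TestGRMs:
    def test_single_site_additive_example(self):
        sm = SampleMatrix(
            dosages=np.array([[2], [0]]),
            site_freq=np.array([0.5]),
            site_effect=np.array([0.1]),
            phenotypes=np.zeros(2),
            genetic_values=np.zeros(2),
        )
        a = grm_additive(sm)
        assert a[0, 1] == pytest.approx(-2.0)  # (2-1)(0-1)/0.5

    def test_single_site_dominance_example(self):
        sm = SampleMatrix(
            dosages=np.array([[1], [1]]),
            site_freq=np.array([0.5]),
            site_effect=np.array([0.1]),
            phenotypes=np.zeros(2),
            genetic_values=np.zeros(2),
        )
        d = grm_dominance(sm)
        assert d[0, 1] == pytest.approx(1.0)  # (0.5 * 0.5) / 0.25

    def test_identical_rows_match_diagonal(self, rng):
        sm = hwe_sample(rng, 4, [0.3, 0.4], [0.1, 0.2])
        sm.dosages[1] = sm.dosages[0]
        a = grm_additive(sm)
        assert a[0, 1] == pytest.approx(a[0, 0])

    def test_hwe_unrelated_sample_properties(self, rng):
        q = rng.uniform(0.05, 0.5, 300)
        sm = hwe_sample(rng, 500, q, np.zeros(300))
        a = grm_additive(sm)
        d = grm_dominance(sm)
        iu = np.triu_indices(500, k=1)
        # mean off-diagonal relatedness ~ 0, diagonal ~ 1
        assert abs(a[iu].mean()) < 0.02
        assert np.mean(np.diag(a)) == pytest.approx(1.0, abs=0.05)
        # additive and dominance relatedness are uncorrelated under HWE
        assert abs(np.corrcoef(a[iu], d[iu])[0, 1]) < 0.05

    def test_all_homref_dominance_rejected(self, rng):
        sm = hwe_sample(rng, 10, [0.2], [0.1])
        sm.dosages[:] = 0
        sm.site_freq = np.array([0.0])
        with pytest.raises(ValueError):
            grm_dominance(sm)


class TestHERegression:
    def test_phenotype_independent_of_genotype(self, rng):
        q = rng.uniform(0.1, 0.5, 100)
        sm = hwe_sample(rng, 800, q, np.zeros(100))
        a = grm_additive(sm)
        y = rng.normal(size=800)
        est, se = he_regression(a, y)
        assert abs(est[0]) < 3 * se[0]

    def test_additive_h2_recovered_at_n6000(self, rng):
        # fully additive synthetic trait, h2 = 0.3, n = 6000
        m = 300
        q = rng.uniform(0.05, 0.5, m)
        alpha = rng.exponential(1.0, m)
        sm = hwe_sample(rng, 6000, q, alpha)
        g = sm.genetic_values
        h2 = 0.3
        sigma_e = np.sqrt(g.var() * (1 - h2) / h2)
        y = g + rng.normal(0, sigma_e, 6000)
        a = grm_additive(sm)
        est, se = he_regression(a, y)
        assert est[0] == pytest.approx(h2, abs=3 * se[0])

    def test_dominance_component_null_on_additive_trait(self, rng):
        m = 200
        q = rng.uniform(0.05, 0.5, m)
        alpha = rng.exponential(1.0, m)
        sm = hwe_sample(rng, 3000, q, alpha)
        g = sm.genetic_values
        y = g + rng.normal(0, g.std(), 3000)
        est, se = he_regression([grm_additive(sm), grm_dominance(sm)], y)
        assert abs(est[1]) < 3 * se[1]
        assert est[0] == pytest.approx(0.5, abs=3 * se[0])

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            he_regression(np.ones((1, 1)), np.ones(1))


class TestLoad:
    def test_examples(self):
        assert genetic_load(np.zeros(10)) == 0.0
        assert genetic_load(np.ones(5), 1.0) == pytest.approx(1 - np.exp(-0.5))
        p = np.array([-1.0, 0.5, 2.0])
        assert genetic_load(p) == pytest.approx(genetic_load(-p))

    def test_burden_ratio(self):
        assert burden_ratio(0.04, 0.04) == 1.0
        assert burden_ratio(0.02, 0.04) == 0.5
        with pytest.raises(ValueError):
            burden_ratio(0.02, 0.0)


class TestSFS:
    def test_all_singletons(self):
        dos = np.zeros((10, 4), dtype=int)
        dos[0] = 1
        spectrum = sfs(dos)
        assert spectrum[0] == 1.0
        assert spectrum.sum() == pytest.approx(1.0)

    def test_lumping_and_normalization(self, rng):
        dos = rng.binomial(2, rng.uniform(0.05, 0.8, 50), size=(30, 50))
        spectrum = sfs(dos, lump_above=18)
        assert len(spectrum) == 19
        assert spectrum.sum() == pytest.approx(1.0)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            sfs(np.zeros((5, 3), dtype=int))


class TestGameteSummaries:
    def test_empty_population_flagged(self, rng):
        from regionsim.simulate import empty_population

        out = gamete_summaries(empty_population(10))
        assert out["mean_count"] == 0.0
        assert np.isnan(out["skew_count"])

    def test_poisson_moments(self, rng):
        # gametes seeded with Poisson(3) mutation counts: skewness 3^-1/2
        from regionsim.core import MutationTable, PopulationState

        n_gam, m = 20_000, 400
        table = MutationTable(
            np.linspace(0, 1, m, endpoint=False), np.ones(m) * 0.1, np.zeros(m, dtype=int)
        )
        occ = (rng.random((n_gam, m)) < 3.0 / m).astype(np.uint8)
        pop = PopulationState(table, occ)
        out = gamete_summaries(pop)
        se = np.sqrt(6.0 / n_gam)
        assert out["skew_count"] == pytest.approx(3 ** -0.5, abs=4 * se + 0.05)
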