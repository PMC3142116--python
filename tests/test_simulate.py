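"""Simulator checks: panels, recombination, trait model, effect calibration."""

import numpy as np
import pytest
from scipy import stats

from famjoint.simulate import (CROSSOVER_RATE, SimulationConfig, beta_from_h,
                               choose_disease_marker, effect_coding,
                               make_families, make_panel, meiosis, recombine,
                               simulate_alt_traits, simulate_cohort,
                               simulate_null_traits)

from conftest import manual_cohort


class CountingRNG:
    """Generator wrapper recording every Poisson draw (crossover counts)."""

    def __init__(self, rng):
        self._rng = rng
        self.poisson_draws = []

    def poisson(self, lam, *args, **kwargs):
        k = self._rng.poisson(lam, *args, **kwargs)
        self.poisson_draws.append((float(lam), int(k)))
        return k

    def __getattr__(self, name):
        return getattr(self._rng, name)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(population="exotic"), "population"),
        (dict(h=1.0), "heritability"),
        (dict(rho=1.0), "rho"),
        (dict(admixture_props=(0.7, 0.2)), "admixture_props"),
        (dict(subpop_fractions=(0.9, 0.2)), "subpop_fractions"),
        (dict(maf_range=(0.0, 0.5)), "maf_range"),
        (dict(maf_range=(0.4, 0.1)), "maf_range"),
    ])
    def test_rejects_bad_values(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimulationConfig(**kwargs)


class TestPanels:
    def test_homogeneous_frequencies_within_range(self):
        cfg = SimulationConfig(population="homogeneous", n_markers=500,
                               maf_range=(0.1, 0.4), seed=1)
        panel = make_panel(cfg)
        assert panel.n_pops == 1
        f = panel.allele_freqs[0]
        assert np.all((f >= 0.1) & (f <= 0.4))
        # haplotype sample frequencies track the panel frequencies
        emp = panel.haplotypes[0].mean(axis=0)
        assert np.corrcoef(emp, f)[0, 1] > 0.9

    def test_structured_fst_matches_hudson_oracle(self):
        cfg = SimulationConfig(population="structured", n_markers=4000,
                               fst=0.15, seed=2)
        panel = make_panel(cfg)
        H = cfg.panel_haplotypes
        p1 = panel.haplotypes[0].mean(axis=0)
        p2 = panel.haplotypes[1].mean(axis=0)
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (H - 1)
               - p2 * (1 - p2) / (H - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst_hat = num.mean() / den.mean()
        assert 0.12 < fst_hat < 0.18

    def test_genetic_map_spans_requested_length(self):
        cfg = SimulationConfig(n_markers=100, map_length=2.8, seed=3)
        panel = make_panel(cfg)
        assert panel.genetic_map[0] > 0
        assert panel.genetic_map[-1] < 2.8
        assert np.all(np.diff(panel.genetic_map) > 0)


class TestRecombination:
    def test_crossover_counts_average_six_per_morgan(self):
        cfg = SimulationConfig(n_markers=50, map_length=2.0, seed=4)
        panel = make_panel(cfg)
        rng = CountingRNG(np.random.default_rng(4))
        h1 = panel.haplotypes[0][0]
        h2 = panel.haplotypes[0][1]
        for _ in range(600):
            meiosis(h1, h2, panel.genetic_map, 2.0, rng)
        lams = {lam for lam, _ in rng.poisson_draws}
        assert lams == {CROSSOVER_RATE * 2.0}
        mean_k = np.mean([k for _, k in rng.poisson_draws])
        # Poisson(12): MC band over 600 draws
        assert abs(mean_k - 12.0) < 4 * np.sqrt(12.0 / 600)

    def test_meiosis_gamete_is_a_haplotype_mosaic(self):
        cfg = SimulationConfig(n_markers=80, map_length=1.5, seed=5)
        panel = make_panel(cfg)
        rng = np.random.default_rng(5)
        h1 = panel.haplotypes[0][2]
        h2 = panel.haplotypes[0][3]
        for _ in range(25):
            g = meiosis(h1, h2, panel.genetic_map, 1.5, rng)
            assert np.all((g == h1) | (g == h2))

    def test_recombinant_draws_from_panel_alleles(self):
        cfg = SimulationConfig(n_markers=60, map_length=1.0, seed=6)
        panel = make_panel(cfg)
        rng = np.random.default_rng(6)
        hp = panel.haplotypes[0]
        for _ in range(25):
            r = recombine(hp, panel.genetic_map, 1.0, rng)
            assert np.all((r[None, :] == hp).any(axis=0) | (r == 0) | (r == 1))
            assert r.min() >= 0 and r.max() <= 1


class TestFamilies:
    def test_structured_subpopulation_counts(self, structured_cohort):
        labels = np.array([f.subpop for f in structured_cohort.families])
        n1 = int((labels == 1).sum())
        # Binomial(300, 0.3): 4-sigma band
        assert abs(n1 - 90) < 4 * np.sqrt(300 * 0.3 * 0.7)

    def test_admixed_ancestry_proportions(self):
        cfg = SimulationConfig(population="admixed", n_families=150,
                               n_markers=40, map_length=2.8, seed=7)
        cohort = make_families(cfg)
        anc = cohort.ancestry_vector
        assert anc is not None and np.all((anc >= 0) & (anc <= 1))
        par = cohort.member_is_parent
        assert abs(anc[par].mean() - 0.8) < 0.03
        # children recorded at the midparent expectation
        fam0 = cohort.families[0]
        assert fam0.ancestry[2] == pytest.approx(
            (fam0.ancestry[0] + fam0.ancestry[1]) / 2.0)

    def test_children_share_parental_haplotypes(self, small_null_cohort):
        # already Mendelian-clean (test_io); here check genotype bounds
        G = small_null_cohort.genotype_matrix
        assert np.nanmin(G) >= 0 and np.nanmax(G) <= 2


@pytest.fixture(scope="module")
def trait_sample():
    cfg = SimulationConfig(population="homogeneous", n_families=4000,
                           children_per_family=2, n_markers=8,
                           map_length=0.1, rho=0.4, seed=8)
    cohort = make_families(cfg)
    rng = np.random.default_rng(8)
    y = simulate_null_traits(cohort, 0.4, rng)
    return y.reshape(4000, 4)  # father, mother, child1, child2


class TestNullTraits:
    def test_parent_moments(self, trait_sample):
        parents = trait_sample[:, :2]
        assert abs(parents.mean()) < 0.05
        assert abs(parents.var() - 1.0) < 0.05
        r_pp = np.corrcoef(trait_sample[:, 0], trait_sample[:, 1])[0, 1]
        assert abs(r_pp) < 0.05

    def test_parent_child_and_sib_correlations(self, trait_sample):
        r_pc = np.corrcoef(trait_sample[:, 0], trait_sample[:, 2])[0, 1]
        r_ss = np.corrcoef(trait_sample[:, 2], trait_sample[:, 3])[0, 1]
        assert abs(r_pc - 0.4) < 0.05
        assert abs(r_ss - 0.4) < 0.05
        assert abs(trait_sample[:, 2:].var() - 1.0) < 0.05

    def test_infeasible_covariance_errors(self):
        rng = np.random.default_rng(0)
        g = np.zeros((1, 1))
        cohort = manual_cohort(
            father=[[1.0]], mother=[[1.0]],
            children=[[[1.0]] * 4],
            traits=[(0, 0, 0, 0, 0, 0)])
        with pytest.raises(ValueError, match="infeasible"):
            simulate_null_traits(cohort, 0.6, rng)


class TestEffects:
    def test_effect_coding_tables(self):
        g = np.array([0, 1, 2])
        np.testing.assert_array_equal(effect_coding(g, "additive"), [0, 1, 2])
        np.testing.assert_array_equal(effect_coding(g, "dominant"), [0, 1, 1])
        np.testing.assert_array_equal(effect_coding(g, "recessive"), [0, 0, 1])
        with pytest.raises(ValueError, match="disease model"):
            effect_coding(g, "overdominant")

    @pytest.mark.parametrize("model", ["additive", "dominant", "recessive"])
    def test_beta_from_h_simulation_oracle(self, model):
        # HWE genotypes at p = 0.3: h_hat = var(beta X)/(var(beta X)+1)
        h, p = 0.1, 0.3
        beta = beta_from_h(h, model, p)
        rng = np.random.default_rng(9)
        g = rng.binomial(2, p, size=400_000)
        v = np.var(beta * effect_coding(g, model))
        assert v / (v + 1.0) == pytest.approx(h, abs=0.004)

    def test_beta_from_h_edges(self):
        assert beta_from_h(0.0, "additive", 0.3) == 0.0
        with pytest.raises(ValueError, match="h"):
            beta_from_h(1.0, "additive", 0.3)
        with pytest.raises(ValueError, match="frequency"):
            beta_from_h(0.1, "additive", 0.0)

    def test_disease_marker_window(self):
        cfg = SimulationConfig(population="structured", n_markers=800,
                               disease_maf_range=(0.1, 0.3), seed=10)
        panel = make_panel(cfg)
        rng = np.random.default_rng(10)
        for _ in range(10):
            m = choose_disease_marker(panel, cfg, rng)
            f = panel.allele_freqs[0, m]
            assert 0.1 < min(f, 1 - f) < 0.3

    def test_disease_marker_window_empty_errors(self):
        cfg = SimulationConfig(n_markers=50, maf_range=(0.31, 0.5),
                               disease_maf_range=(0.1, 0.3), seed=11)
        panel = make_panel(cfg)
        with pytest.raises(ValueError, match="MAF"):
            choose_disease_marker(panel, cfg, np.random.default_rng(0))

    def test_realized_heritability_among_founders(self):
        cfg = SimulationConfig(population="homogeneous", n_families=3000,
                               n_markers=30, map_length=0.2, h=0.2,
                               disease_model="additive", seed=12)
        cohort = simulate_cohort(cfg)
        ypar = cohort.trait_vector[cohort.member_is_parent]
        h_hat = 1.0 - 1.0 / np.var(ypar)   # var = 1 + beta^2 Var(X)
        assert abs(h_hat - 0.2) < 0.05

    def test_h_without_model_errors(self):
        cfg = SimulationConfig(h=0.1, n_families=10, n_markers=20,
                               map_length=0.2, seed=13)
        with pytest.raises(ValueError, match="disease model"):
            simulate_cohort(cfg)


class TestStructureShifts:
    def test_subpopulation_mean_difference_is_mu(self, structured_cohort):
        y = structured_cohort.trait_vector
        pops = np.repeat([f.subpop for f in structured_cohort.families],
                         2 + structured_cohort.children_per_family)
        diff = y[pops == 1].mean() - y[pops == 0].mean()
        assert diff == pytest.approx(2.0, abs=0.25)

    def test_ancestry_slope_is_mu(self):
        cfg = SimulationConfig(population="admixed", n_families=600,
                               n_markers=40, map_length=2.8, mu=2.0, seed=14)
        cohort = simulate_cohort(cfg)
        par = cohort.member_is_parent
        slope = np.polyfit(cohort.ancestry_vector[par],
                           cohort.trait_vector[par], 1)[0]
        assert slope == pytest.approx(2.0, abs=0.5)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = SimulationConfig(population="structured", n_families=40,
                               n_markers=60, map_length=1.0, mu=1.0, seed=15)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(a.genotype_matrix, b.genotype_matrix)
        np.testing.assert_array_equal(a.trait_vector, b.trait_vector)

    def test_different_seed_differs(self):
        base = dict(population="homogeneous", n_families=40, n_markers=60,
                    map_length=1.0)
        a = simulate_cohort(SimulationConfig(seed=16, **base))
        b = simulate_cohort(SimulationConfig(seed=17, **base))
        assert not np.array_equal(a.genotype_matrix, b.genotype_matrix)
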