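import numpy as np
import pytest
from scipy import stats

from waspqg.selection import (
    MatingFailureError,
    SimConfig,
    assay_cohort,
    assay_phenotype,
    breed_next_generation,
    init_base_population,
    run_experiment,
    truncation_select,
)
from waspqg.synthetic import va_for_h2
from waspqg.tables import rng_from_seed


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(selected_per_generation=200, females_per_line=100)
        with pytest.raises(ValueError):
            SimConfig(true_Va=-1)
        with pytest.raises(ValueError):
            SimConfig(baseline_host_survival=0.9, host_survival_final_ratio=1.3)

    def test_survival_path(self):
        cfg = SimConfig()
        s0 = cfg.baseline_host_survival
        assert cfg.host_survival_at(0) == cfg.host_survival_at(2) == s0
        assert cfg.host_survival_at(7) == pytest.approx(1.3 * s0)
        assert cfg.host_resistance_at(2) == 0.0
        assert cfg.host_resistance_at(7) == cfg.host_resistance_final_shift

    def test_latent_h2(self):
        cfg = SimConfig(true_Va=2.0, true_Vday=0.0, true_Vmother=0.0)
        assert cfg.true_latent_h2 == pytest.approx(0.5)


class TestBasePopulation:
    def test_zero_variance_zero_breeding_values(self):
        cfg = SimConfig(true_Va=0.0)
        pop = init_base_population(cfg, rng_from_seed(1))
        assert np.all(pop.breeding_values() == 0)

    def test_founder_variance_scaled(self):
        cfg = SimConfig(true_Va=1.0, females_per_line=10_000)
        pop = init_base_population(cfg, rng_from_seed(2))
        assert pop.breeding_values().var() == pytest.approx(1.0, abs=0.05)


class TestAssay:
    def test_no_killing_full_survival(self):
        cfg = SimConfig(true_Va=0.0, base_mean_liability=-30.0)
        rng = rng_from_seed(3)
        f, e, p, _ = assay_phenotype(0.0, 0.0, 1.0, cfg, rng)
        assert f == 25 and e <= f and p == 0

    def test_total_killing_no_survivors(self):
        cfg = SimConfig(true_Va=0.0, base_mean_liability=30.0)
        rng = rng_from_seed(4)
        f, _, _, _ = assay_phenotype(0.0, 0.0, 1.0, cfg, rng)
        assert f == 0

    def test_mean_emergence_at_liability_zero(self):
        # q = Phi(0) = 0.5 on average, host survival 0.8: E[f]/25 = 0.4
        cfg = SimConfig(
            true_Va=0.0, true_Vday=0.0, true_Vmother=0.0,
            base_mean_liability=0.0, baseline_host_survival=0.8,
            host_survival_final_ratio=1.0, females_per_line=20_000,
            selected_per_generation=100,
        )
        pop = init_base_population(cfg, rng_from_seed(5))
        trials, _, liab, _ = assay_cohort(pop, 0, cfg, rng_from_seed(6))
        frac = trials["flies_emerged"].mean() / 25
        # E[Phi(Z)] = 0.5 for Z ~ N(0,1); residual keeps per-female q varying
        assert frac == pytest.approx(0.8 * 0.5, abs=0.01)


class TestTruncationSelect:
    def test_top_k_exact(self):
        vals = np.array([5.0, 1.0, 9.0, 3.0])
        sel = truncation_select(vals, 2, rng_from_seed(7))
        assert set(sel) == {0, 2}

    def test_k_equals_n_identity(self):
        vals = np.arange(6.0)
        assert set(truncation_select(vals, 6, rng_from_seed(8))) == set(range(6))

    def test_tie_break_uniform(self):
        vals = np.zeros(4)
        counts = np.zeros(4)
        for s in range(4000):
            sel = truncation_select(vals, 1, rng_from_seed(9, s))
            counts[sel[0]] += 1
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert stats.chi2(3).sf(chi2) > 0.01

    def test_k_validation(self):
        with pytest.raises(ValueError):
            truncation_select(np.arange(3.0), 0, rng_from_seed(1))
        with pytest.raises(ValueError):
            truncation_select(np.arange(3.0), 4, rng_from_seed(1))


class TestBreeding:
    def test_transmission_mean(self):
        """Mean offspring breeding value matches the parental gametic
        expectation: mothers contribute half their value, sires all of
        theirs (haploid), so E[g_daughter] = mean(g_mothers)/2 + mean(g_sires)."""
        cfg = SimConfig(
            true_Va=1.0, females_per_line=5000, males_per_line=5000,
            selected_per_generation=2500, pupae_per_mother=4,
        )
        rng = rng_from_seed(10)
        pop = init_base_population(cfg, rng)
        mothers = np.arange(5000)
        off = breed_next_generation(pop, mothers, cfg, rng)
        expect = pop.breeding_values()[mothers].mean() / 2 + pop.male_h.sum(axis=1).mean()
        se = np.sqrt(1.0 / off.n_females) * 3
        assert off.breeding_values().mean() == pytest.approx(expect, abs=3 * se)

    def test_sister_covariances_match_amatrix(self):
        """Genotype-explicit transmission reproduces the haplodiploid
        relationship matrix: full sisters 0.75 Va, paternal half sisters
        0.5 Va."""
        va = 1.0
        n_fam = 10_000
        cfg = SimConfig(
            true_Va=va, females_per_line=n_fam, males_per_line=n_fam,
            selected_per_generation=n_fam // 2, pupae_per_mother=2, sex_ratio=1.0,
        )
        rng = rng_from_seed(11)
        pop = init_base_population(cfg, rng)
        L = cfg.n_loci
        sires = rng.integers(0, n_fam, size=n_fam)
        gam1 = np.where(
            rng.integers(0, 2, (n_fam, L)) == 0, pop.female_h[:, 0, :], pop.female_h[:, 1, :]
        )
        gam2 = np.where(
            rng.integers(0, 2, (n_fam, L)) == 0, pop.female_h[:, 0, :], pop.female_h[:, 1, :]
        )
        sire_h = pop.male_h[sires]
        g_full_1 = (gam1 + sire_h).sum(axis=1)
        g_full_2 = (gam2 + sire_h).sum(axis=1)
        cov_full = np.cov(g_full_1, g_full_2)[0, 1]
        se = 3 * va / np.sqrt(n_fam)
        assert cov_full == pytest.approx(0.75 * va, abs=3 * se)
        # paternal half sisters: same sire, unrelated dams
        other = np.roll(np.arange(n_fam), 1)
        g_half = (gam2[other] + sire_h).sum(axis=1)
        cov_half = np.cov(g_full_1, g_half)[0, 1]
        assert cov_half == pytest.approx(0.5 * va, abs=3 * se)

    def test_no_sons_raises(self):
        cfg = SimConfig(
            females_per_line=20, males_per_line=20, selected_per_generation=10,
            pupae_per_mother=8, sex_ratio=1.0,
        )
        rng = rng_from_seed(12)
        pop = init_base_population(cfg, rng)
        with pytest.raises(MatingFailureError, match="male"):
            breed_next_generation(pop, np.arange(10), cfg, rng)

    def test_too_few_daughters_raises(self):
        cfg = SimConfig(
            females_per_line=100, males_per_line=20, selected_per_generation=5,
            pupae_per_mother=2,
        )
        rng = rng_from_seed(13)
        pop = init_base_population(cfg, rng)
        with pytest.raises(MatingFailureError, match="daughters"):
            breed_next_generation(pop, np.arange(5), cfg, rng)


class TestExperiment:
    def _small(self, **kw):
        base = dict(
            n_lines_selected=1, n_lines_control=1, females_per_line=60,
            males_per_line=60, selected_per_generation=30, generations=4,
            host_survival_final_ratio=1.0, host_resistance_final_shift=0.0,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_records_shape_and_determinism(self):
        cfg = self._small(seed=3)
        t1, t2 = run_experiment(cfg), run_experiment(cfg)
        assert len(t1.records) == 2 * 5  # 2 lines x (P..F4)
        m1, m2 = t1.means_table(), t2.means_table()
        assert np.allclose(m1["mean_all"], m2["mean_all"])

    def test_null_genetics_no_response(self):
        slopes = []
        for seed in range(6):
            cfg = self._small(true_Va=0.0, seed=seed)
            mt = run_experiment(cfg).means_table("selection")
            mt = mt.sort_values("generation")
            slopes.append(np.polyfit(mt["generation"], mt["mean_all"], 1)[0])
        assert abs(np.mean(slopes)) < 1.5  # percent per generation

    def test_positive_response_under_heritable_variation(self):
        va = va_for_h2(0.28)
        gains = []
        for seed in range(6):
            cfg = self._small(true_Va=va, females_per_line=100,
                              selected_per_generation=50, males_per_line=100,
                              generations=5, seed=seed)
            mt = run_experiment(cfg).means_table("selection").sort_values("generation")
            gains.append(mt["mean_all"].iloc[-1] - mt["mean_all"].iloc[0])
        assert np.mean(gains) > 0
        assert sum(g > 0 for g in gains) >= 4

    def test_control_lines_flat(self):
        va = va_for_h2(0.28)
        slopes = []
        for seed in range(6):
            cfg = self._small(true_Va=va, seed=seed, generations=5)
            mt = run_experiment(cfg).means_table("control").sort_values("generation")
            slopes.append(np.polyfit(mt["generation"], mt["mean_all"], 1)[0])
        assert abs(np.mean(slopes)) < 1.5

    def test_latent_realized_h2_matches_transmission_recursion(self):
        """Selecting directly on liability with the host environment fixed,
        the cumulative latent response follows the deterministic
        single-parent transmission recursion.

        Only mothers are phenotyped and selected; the sires of each
        generation are sons of the previously selected mothers.  A daughter
        takes half her genome from her dam and all of her sire's (haploid)
        genome, so with a constant latent differential S and accuracy
        b = Va / Var(l) the mean breeding value follows

            m_{t+1} = (m_t + b S)/2 + mu_t,   mu_{t+1} = (m_t + b S)/2,

        approaching a per-generation gain of (2/3) b S.  The regression
        through the origin of cumulative response on cumulative S must
        match the slope this recursion implies."""
        va, vmother, gens = 1.0, 0.001, 5
        b = va / (va + vmother + 1.0)  # selection accuracy on the liability
        slopes = []
        for seed in range(8):
            cfg = SimConfig(
                n_lines_selected=1, n_lines_control=0, females_per_line=2000,
                males_per_line=2000, selected_per_generation=1000,
                generations=gens, true_Va=va, true_Vday=0.0,
                host_survival_final_ratio=1.0, host_resistance_final_shift=0.0,
                seed=seed,
            )
            rng = rng_from_seed(cfg.seed, 1, 0)
            pop = init_base_population(cfg, rng)
            S, R, g_means = [], [], []
            for t in range(gens + 1):
                _, _, liab, _ = assay_cohort(pop, t, cfg, rng)
                g_means.append(pop.breeding_values().mean())
                sel = truncation_select(liab, cfg.selected_per_generation, rng)
                if t < gens:
                    S.append(liab[sel].mean() - liab.mean())
                    pop = breed_next_generation(pop, sel, cfg, rng)
            R = np.diff(g_means)
            x, y = np.cumsum(S), np.cumsum(R)
            slopes.append((x @ y) / (x @ x))
        # oracle: run the recursion at unit differential
        m = mu = 0.0
        m_path = []
        for _ in range(gens):
            m, mu = (m + b) / 2.0 + mu, (m + b) / 2.0
            m_path.append(m)
        t = np.arange(1, gens + 1, dtype=float)
        expected = (t @ np.array(m_path)) / (t @ t)
        assert np.mean(slopes) == pytest.approx(expected, abs=0.05)
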