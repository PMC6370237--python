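"""Structural and distributional tests of the population generator."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from lethalmap.popsim import (
    LegWeaknessModel,
    QuantTrait,
    SimConfig,
    SnpPanelConfig,
    TraitModel,
    assign_phenotypes,
    cohort_counts,
    deterministic_recursion,
    simulate_population,
)


class TestRecursion:
    def test_lethal_with_carrier_advantage_equilibrium(self):
        traj, q_star, ok = deterministic_recursion(s1=0.25, s2=1.0, q0=0.5, n_gen=200)
        assert ok and q_star == pytest.approx(0.2)
        assert traj[-1] == pytest.approx(q_star, abs=1e-6)

    def test_plain_lethal_declines_monotonically(self):
        traj, q_star, ok = deterministic_recursion(s1=0.0, s2=1.0, q0=0.22, n_gen=30)
        assert np.all(np.diff(traj) < 0)
        assert q_star == 0.0
        # classical decline q_t = q0 / (1 + t*q0)
        t = np.arange(31)
        np.testing.assert_allclose(traj, 0.22 / (1 + t * 0.22), atol=1e-12)

    def test_inverted_closed_form_reaches_observed_frequency(self):
        # the s1 that balances a full lethal at q* = 0.22 is q*/(1-q*)
        s1 = 0.22 / 0.78
        traj, q_star, ok = deterministic_recursion(s1=s1, s2=1.0, q0=0.5, n_gen=300)
        assert q_star == pytest.approx(0.22, abs=1e-9)
        assert traj[-1] == pytest.approx(0.22, abs=1e-6)

    def test_neutral_case_flagged_undefined(self):
        traj, q_star, ok = deterministic_recursion(0.0, 0.0, 0.22, 10)
        assert not ok and q_star == 0.22
        assert np.all(traj == 0.22)


class TestSimulate:
    def test_q0_zero_means_no_lethal_alleles(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, q0=0.0)
        pop = simulate_population(cfg)
        assert pop.causal_genotypes.sum() == 0
        assert pop.phenotypes["leg_weakness"].sum() == 0

    def test_no_tt_survives_to_110kg(self, sim_pop):
        g = sim_pop.causal_genotypes
        alive = sim_pop.stage_flags["alive_110kg"].to_numpy()
        assert ((g == 2) & alive).sum() == 0

    def test_birth_cohort_in_hwe_over_replicate_seeds(self):
        """Zygote genotype frequencies at birth are Hardy-Weinberg; the 5%
        critical value should be exceeded in roughly 1/10 of replicates."""
        # many sires/dams with small litters: the zygote cohort then behaves
        # like ~independent draws from random mating (few large full-sib
        # litters leave the chi-square overdispersed)
        cfg = SimConfig(
            n_founders=300, n_generations=2, n_sires=100, n_dams=140,
            litter_mean=4.0,
            survival_40kg=(0.95, 0.95, 0.02), survival_110kg=(0.9, 0.9, 0.0),
            snp_panel=SnpPanelConfig(n_snps=12, chrom_lengths_bp=(50_000_000,)),
            causal_chrom=1, causal_pos_bp=25_000_000,
        )
        n_reject = 0
        for seed in range(10):
            pop = simulate_population(dataclasses.replace(cfg, seed=seed))
            t = pop.pedigree.table
            born = (t["generation"] == 1).to_numpy()
            g = pop.causal_genotypes[born]
            counts = np.bincount(g, minlength=3)
            from lethalmap.hwe import cohort_stats

            cs = cohort_stats(*counts)
            assert len(g) >= 400
            if cs.chi2 > stats.chi2.ppf(0.95, 1):
                n_reject += 1
        assert n_reject <= 2

    def test_mean_trajectory_tracks_deterministic_recursion(self):
        """Birth-cohort allele frequency under viability-only dynamics (no
        index selection, full TT lethality) follows the deterministic
        recursion with s1=0, s2=1 within 3 Monte-Carlo SE per generation."""
        cfg = SimConfig(
            n_founders=60, n_generations=4, n_sires=10, n_dams=20,
            litter_mean=7.0, q0=0.3, index_weights=(0.0, 0.0), index_noise_sd=1.0,
            survival_40kg=(0.95, 0.95, 0.0), survival_110kg=(0.9, 0.9, 0.0),
            snp_panel=SnpPanelConfig(n_snps=6, chrom_lengths_bp=(50_000_000,)),
            causal_chrom=1, causal_pos_bp=25_000_000,
        )
        n_rep = 50
        qs = np.full((n_rep, cfg.n_generations), np.nan)
        for r in range(n_rep):
            pop = simulate_population(dataclasses.replace(cfg, seed=1000 + r))
            t = pop.pedigree.table
            g = pop.causal_genotypes
            for gen in range(cfg.n_generations):
                m = (t["generation"] == gen).to_numpy()
                qs[r, gen] = g[m].mean() / 2
        traj, _, _ = deterministic_recursion(0.0, 1.0, cfg.q0, cfg.n_generations - 1)
        mean_q = qs.mean(axis=0)
        se = qs.std(axis=0, ddof=1) / np.sqrt(n_rep)
        for gen in range(1, cfg.n_generations):
            assert abs(mean_q[gen] - traj[gen]) < 3 * max(se[gen], 1e-4), (
                f"generation {gen}: {mean_q[gen]:.4f} vs {traj[gen]:.4f}"
            )

    def test_tt_homozygous_across_ibd_window(self, sim_pop):
        cfg = sim_pop.config
        sm = sim_pop.snp_map
        win = (sm["chrom"].to_numpy() == cfg.causal_chrom) & (
            np.abs(sm["pos"].to_numpy() - cfg.causal_pos_bp) <= cfg.ibd_window_bp
        )
        tt = sim_pop.causal_genotypes == 2
        assert tt.sum() > 0
        h = sim_pop.haplotypes[tt][:, :, win]
        assert (h[:, 0, :] == h[:, 1, :]).all()
        # and identical across individuals (single ancestral origin)
        assert (h[:, 0, :] == h[0, 0, :]).all()

    def test_config_rejection(self):
        with pytest.raises(ValueError, match="litter_mean"):
            simulate_population(SimConfig(litter_mean=0))
        with pytest.raises(ValueError, match="outside"):
            simulate_population(SimConfig(causal_pos_bp=10**10))

    def test_cohort_counts_stages(self, sim_pop):
        cc = cohort_counts(sim_pop)
        assert list(cc["stage"]) == ["birth", "40kg", "110kg"]
        assert (cc[["n_GG", "n_GT", "n_TT"]].sum(axis=1).diff().dropna() <= 0).all()


class TestAssignPhenotypes:
    def test_zero_variance_phenotypes_deterministic(self, sim_pop):
        model = TraitModel(
            leg_weakness=LegWeaknessModel(penetrance=1.0),
            muscle_depth=QuantTrait(48.38, 53.21, None, 0.0, 0.0, 0.0, 0.0),
            fat_depth=QuantTrait(10.19, 8.42, None, 0.0, 0.0, 0.0, 0.0),
            live_weight=QuantTrait(87.13, 84.89, None, 0.0, 0.0, 0.0, 0.0),
        )
        ph = assign_phenotypes(sim_pop, model, seed=1)
        g = sim_pop.causal_genotypes
        np.testing.assert_array_equal(ph["leg_weakness"].to_numpy(), (g == 2).astype(float))
        means = model.muscle_depth.genotype_means()
        np.testing.assert_allclose(ph["muscle_depth"].to_numpy(), means[g])

    def test_carrier_mean_difference_recovered(self, sim_pop):
        delta = 4.83
        model = TraitModel(
            muscle_depth=QuantTrait(48.38, 48.38 + delta, None, 0.0, 0.0, 0.0, 9.0)
        )
        ph = assign_phenotypes(sim_pop, model, seed=2)
        g = sim_pop.causal_genotypes
        m_gt = ph.loc[g == 1, "muscle_depth"]
        m_gg = ph.loc[g == 0, "muscle_depth"]
        diff = m_gt.mean() - m_gg.mean()
        se = np.sqrt(m_gt.var() / len(m_gt) + m_gg.var() / len(m_gg))
        assert abs(diff - delta) < 3 * se

    def test_litter_variance_gives_intraclass_correlation(self, sim_pop):
        s2v, s2e = 3.0, 7.0
        model = TraitModel(
            muscle_depth=QuantTrait(50.0, 50.0, 50.0, 0.0, s2v, 0.0, s2e)
        )
        ph = assign_phenotypes(sim_pop, model, seed=3)
        ph = ph[ph["litter"] != 0]
        grand = ph["muscle_depth"].mean()
        # intraclass correlation via one-way ANOVA components
        groups = ph.groupby("litter")["muscle_depth"]
        k = groups.size()
        between = (k * (groups.mean() - grand) ** 2).sum() / (len(k) - 1)
        within = groups.apply(lambda x: ((x - x.mean()) ** 2).sum()).sum() / (len(ph) - len(k))
        k0 = (len(ph) - (k**2).sum() / len(ph)) / (len(k) - 1)
        icc = (between - within) / k0 / ((between - within) / k0 + within)
        assert icc == pytest.approx(s2v / (s2v + s2e), abs=0.06)

    def test_zero_variances_make_affected_exact_tt_indicator(self, sim_pop):
        model = TraitModel(leg_weakness=LegWeaknessModel(penetrance=1.0))
        ph = assign_phenotypes(sim_pop, model, seed=4)
        np.testing.assert_array_equal(
            ph["leg_weakness"].to_numpy(), (sim_pop.causal_genotypes == 2).astype(float)
        )
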