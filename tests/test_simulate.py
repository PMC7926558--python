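import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omega3sig as o
from omega3sig.simulate import _nb_sample


class TestHepatocyteExperiment:
    def test_deterministic_under_fixed_seed(self, spec, hepatocyte):
        cm2, design2, _, truth2 = o.simulate_hepatocyte_experiment(spec)
        cm1, _, _, truth1 = hepatocyte
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(truth1.genes, truth2.genes)

    def test_lnc_fraction_arithmetic(self, hepatocyte):
        _, _, genes, _ = hepatocyte
        assert len(genes.genes_of_biotype("lncRNA")) == 400

    def test_vehicle_has_no_planted_effect(self, hepatocyte):
        _, design, _, truth = hepatocyte
        # truth stores per-condition lfc only; vehicle columns do not exist,
        # and every venn class is populated per quota
        counts = truth.genes["venn_class"].value_counts()
        for cls in ("DHA", "EPA", "OA", "DHA_EPA", "DHA_OA", "EPA_OA",
                    "DHA_EPA_OA"):
            assert counts[cls] > 0

    def test_null_plant_means_ratio_one(self):
        spec = o.SimSpec(rng_seed=3, n_genes=300, venn_quotas={}, frac_silent=0.0)
        cm, design, _, truth = o.simulate_hepatocyte_experiment(spec)
        assert (truth.genes[["lfc_DHA", "lfc_EPA", "lfc_OA"]] == 0).all().all()
        cpm = o.cpm(cm).values
        dha = cpm[design.samples_of("DHA")].mean(axis=1)
        veh = cpm[design.samples_of("vehicle")].mean(axis=1)
        expressed = truth.genes["baseline_mean"] > 50
        ratio = (dha[expressed] / veh[expressed]).median()
        assert abs(np.log2(ratio)) < 0.1

    def test_rep_floor(self, spec):
        with pytest.raises(ValueError, match="n_reps"):
            o.simulate_hepatocyte_experiment(spec.replace(n_reps=1))

    def test_planted_mean_recovered_across_seed_replicates(self):
        """A gene planted at log2FC=+2 from baseline 100 shows a 4x mean."""
        n_rep_seeds, n_reps, base = 200, 5, 100.0
        means = []
        for seed in range(n_rep_seeds):
            rng = np.random.default_rng(seed)
            phi = np.full(n_reps, 0.02 + 2.0 / base)
            means.append(_nb_sample(rng, np.full(n_reps, base * 4.0), phi).mean())
        emp = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(n_rep_seeds)
        assert abs(emp - 400.0) < 4 * se

    def test_nb_moments_match_planted(self):
        """Empirical NB mean and variance match (mu, mu + phi mu^2)."""
        rng = np.random.default_rng(0)
        mu, phi, n = 150.0, 0.08, 120
        draws = np.array([_nb_sample(rng, np.full(50, mu), np.full(50, phi)).astype(float)
                          for _ in range(n)]).ravel()
        m_se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - mu) < 3 * m_se
        target_var = mu + phi * mu ** 2
        # variance of the sample variance for NB via moments of the draws
        v_se = np.sqrt(np.var((draws - draws.mean()) ** 2, ddof=1) / draws.size)
        assert abs(draws.var(ddof=1) - target_var) < 3 * v_se


class TestPopulationCohort:
    def test_identical_seed_identical_matrices(self, spec, general_cohort):
        cm2, _ = o.simulate_population_cohort(spec, "general")
        pd.testing.assert_frame_equal(general_cohort[0].counts, cm2.counts)

    def test_cv_recovery(self, cfg, general_cohort):
        cm, truth = general_cohort
        genes = o.GeneTable.from_records(truth.genes.index.tolist(),
                                         truth.genes["biotype"].tolist())
        table = o.population_cv(o.cpm(cm), genes, cfg, "general")
        rho = stats.spearmanr(truth.genes.loc[table.index, "pop_cv_general"],
                              table["cv"]).statistic
        assert rho >= 0.8

    def test_near_zero_plant_lands_in_lowest_stratum(self, cfg):
        spec = o.SimSpec(rng_seed=5, cv_plant_least=(1e-4, 2e-4))
        cm, truth = o.simulate_population_cohort(spec, "general")
        genes = o.GeneTable.from_records(truth.genes.index.tolist(),
                                         truth.genes["biotype"].tolist())
        table = o.population_cv(o.cpm(cm), genes, cfg, "general")
        planted = truth.genes.index[truth.genes["plant_stratum"] == "least"]
        planted = [g for g in planted if g in table.index]
        assert planted
        assert (table.loc[planted, "stratum"] == "least_variable").all()

    def test_cohort_size_floor(self, spec):
        with pytest.raises(ValueError):
            o.simulate_population_cohort(spec.replace(n_disease=2), "disease")


class TestDonorPanel:
    def test_degenerate_panel_equals_planted_fold_change(self, spec, hepatocyte):
        _, _, _, truth = hepatocyte
        gene = truth.genes.index[truth.genes["lfc_DHA"] != 0][0]
        quiet = spec.replace(kappa=0.0, donor_base_var=0.0, n_donors=1)
        panel = o.simulate_donor_panel(quiet, truth, [gene])
        expected = 2.0 ** truth.genes.loc[gene, "lfc_DHA"]
        assert panel.iloc[0, 0] == pytest.approx(expected)

    def test_unknown_gene_rejected(self, spec, hepatocyte):
        _, _, _, truth = hepatocyte
        with pytest.raises(ValueError, match="nope"):
            o.simulate_donor_panel(spec, truth, ["nope"])

    def test_null_coupling_gives_no_structure(self, hepatocyte):
        """With kappa=0, response CV is uncorrelated with population CV."""
        _, _, _, truth = hepatocyte
        genes = truth.genes.index[truth.genes["plant_stratum"].isin(
            ["most", "least"])][:24].tolist()
        n_sig = 0
        for seed in range(100):
            spec0 = o.SimSpec(rng_seed=seed, kappa=0.0)
            panel = o.simulate_donor_panel(spec0, truth, genes)
            resp = o.response_cv(panel)
            r, p = stats.pearsonr(truth.genes.loc[genes, "pop_cv_general"], resp)
            n_sig += p < 0.05
        assert n_sig <= 10  # >=90% of seeds non-significant

    def test_default_coupling_recovered(self, spec, hepatocyte):
        _, _, _, truth = hepatocyte
        genes = truth.genes.index[truth.genes["plant_stratum"].isin(
            ["most", "least"])][:24].tolist()
        panel = o.simulate_donor_panel(spec, truth, genes)
        resp = o.response_cv(panel)
        r, p = stats.pearsonr(truth.genes.loc[genes, "pop_cv_general"], resp)
        assert r > 0 and p < 0.05


class TestExosomeReads:
    def test_no_mouse_reads_all_human(self, spec, hepatocyte):
        _, _, genes, _ = hepatocyte
        combined = o.with_mouse_genes(genes, 50)
        quiet = spec.replace(n_mouse_reads=0, n_ambiguous=0,
                             mouse_secondary_frac=0.0, n_human_reads=2000)
        records, _ = o.simulate_exosome_reads(quiet, combined)
        origins = o.assign_origin(records)
        assert (origins["origin"] == "human").all()

    def test_ambiguous_reads_have_two_equal_score_records(self, spec, hepatocyte):
        _, _, genes, _ = hepatocyte
        combined = o.with_mouse_genes(genes, 50)
        small = spec.replace(n_human_reads=500, n_mouse_reads=100, n_ambiguous=100)
        records, truth = o.simulate_exosome_reads(small, combined)
        amb = truth.reads.loc[truth.reads["true_origin"] == "ambiguous", "read_id"]
        assert len(amb) == 100
        sub = records[records["read_id"].isin(set(amb))]
        per_read = sub.groupby("read_id").agg(n=("contig", "size"),
                                              scores=("score", "nunique"))
        assert (per_read["n"] == 2).all() and (per_read["scores"] == 1).all()

    def test_planted_top_quintile_recovered_exactly(self, spec, hepatocyte, cfg):
        _, _, genes, _ = hepatocyte
        combined = o.with_mouse_genes(genes, spec.n_mouse_genes)
        records, truth = o.simulate_exosome_reads(spec, combined)
        origins = o.assign_origin(records)
        counts = o.quantify_human_genes(origins, combined)
        full = counts.reindex(combined.genes_of_species("human"), fill_value=0.0)
        detected = set(o.top_fraction(full, cfg.exo_top_frac))
        planted = set(truth.genes.index[truth.genes["exo_top"]])
        assert detected == planted
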