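import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omega3sig as o
from omega3sig import variability
from omega3sig.normalize import ExpressionMatrix
from conftest import truth_calls


def _expr(rows, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                     columns=samples, dtype=float), "cpm")


class TestPopulationCv:
    def test_hand_arithmetic(self, cfg):
        genes = o.GeneTable.from_records(["g", "h"], "protein_coding")
        expr = _expr([[1, 2, 3], [5, 5, 5]], ["g", "h"], list("abc"))
        table = o.population_cv(expr, genes, cfg, "general")
        assert table.loc["g", "cv"] == pytest.approx(0.5)  # sd 1 (n-1), mean 2
        assert table.loc["h", "cv"] == pytest.approx(0.0)

    def test_constant_gene_in_least_stratum(self, cfg):
        genes = o.GeneTable.from_records([f"g{i}" for i in range(8)],
                                         "protein_coding")
        rng = np.random.default_rng(0)
        rows = rng.uniform(2, 50, size=(8, 6))
        rows[0] = 5.0
        expr = _expr(rows, [f"g{i}" for i in range(8)], list("abcdef"))
        table = o.population_cv(expr, genes, cfg, "general")
        assert table.loc["g0", "stratum"] == "least_variable"

    def test_scale_invariance(self, cfg):
        genes = o.GeneTable.from_records(["g"], "protein_coding")
        base = _expr([[2, 4, 9]], ["g"], list("abc"))
        scaled = _expr([[20, 40, 90]], ["g"], list("abc"))
        cv1 = o.population_cv(base, genes, cfg, "general").loc["g", "cv"]
        cv2 = o.population_cv(scaled, genes, cfg, "general").loc["g", "cv"]
        assert cv1 == pytest.approx(cv2)


class TestStratify:
    def test_sizes_are_floor_of_quantile(self):
        cv = pd.Series(np.linspace(0, 2, 103),
                       index=pd.Index([f"g{i:03d}" for i in range(103)],
                                      name="gene_id"))
        s = o.stratify(cv, 0.25)
        assert (s == "least_variable").sum() == 25  # floor(0.25*103)
        assert (s == "most_variable").sum() == 25

    def test_ties_broken_by_gene_id(self):
        cv = pd.Series([1.0] * 4,
                       index=pd.Index(["d", "c", "b", "a"], name="gene_id"))
        s = o.stratify(cv, 0.25)
        assert s["a"] == "least_variable"
        assert s["d"] == "most_variable"


class TestStratifiedIntersection:
    def _var(self, strata, cohort):
        idx = pd.Index(list(strata), name="gene_id")
        return pd.DataFrame({"cohort": cohort, "cv": 1.0,
                             "stratum": list(strata.values())}, index=idx)

    def test_requires_membership_in_both_cohorts(self):
        gen = self._var({"g": "most_variable"}, "general")
        dis = self._var({"g": "middle"}, "disease")
        assign = pd.DataFrame({"signature_class": ["DHA_only"]},
                              index=pd.Index(["g"], name="gene_id"))
        out = o.stratified_signature_intersection(
            {"general": gen, "disease": dis}, assign)
        row = out.set_index("signature_class").loc["DHA_only"]
        assert row["n_most_variable"] == 0

    def test_empty_class_zero_row(self):
        gen = self._var({"g": "most_variable"}, "general")
        assign = pd.DataFrame({"signature_class": ["DHA_only"]},
                              index=pd.Index(["g"], name="gene_id"))
        out = o.stratified_signature_intersection({"general": gen}, assign)
        row = out.set_index("signature_class").loc["EPA_only"]
        assert row["n_most_variable"] == 0 and row["n_least_variable"] == 0

    def test_disjoint_universes_rejected(self):
        gen = self._var({"g": "middle"}, "general")
        dis = self._var({"h": "middle"}, "disease")
        with pytest.raises(ValueError, match="disjoint"):
            o.stratified_signature_intersection(
                {"general": gen, "disease": dis},
                pd.DataFrame({"signature_class": []}))

    def test_planted_ratios_recovered(self, spec, cfg, general_cohort,
                                      disease_cohort):
        """Planted 12x/7x/4x most:least ratios read back exactly."""
        cm_g, truth = general_cohort
        cm_d, _ = disease_cohort
        genes = o.GeneTable.from_records(truth.genes.index.tolist(),
                                         truth.genes["biotype"].tolist())
        var = {
            "general": o.population_cv(o.cpm(cm_g), genes, cfg, "general"),
            "disease": o.population_cv(o.cpm(cm_d), genes, cfg, "disease"),
        }
        assign = pd.DataFrame(
            {"signature_class": truth.genes["signature_class"]})
        out = o.stratified_signature_intersection(var, assign)
        ratios = out.set_index("signature_class")["ratio_most_to_least"]
        for cls, target in [("DHA_and_EPA", 12.0), ("DHA_only", 7.0),
                            ("EPA_only", 4.0)]:
            assert abs(ratios[cls] - target) <= 0.2 * target


class TestResponseCv:
    def test_hand_arithmetic(self):
        panel = pd.DataFrame([[1.0, 2.0, 3.0]],
                             index=pd.Index(["g"], name="gene_id"),
                             columns=["d1", "d2", "d3"])
        assert o.response_cv(panel)["g"] == pytest.approx(0.5)

    def test_identical_ratios_zero(self):
        panel = pd.DataFrame([[2.0] * 5], index=pd.Index(["g"]),
                             columns=[f"d{i}" for i in range(5)])
        assert o.response_cv(panel)["g"] == 0.0

    def test_donor_permutation_invariant(self):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(rng.lognormal(0, 0.5, (4, 6)),
                             index=pd.Index(list("abcd")),
                             columns=[f"d{i}" for i in range(6)])
        shuffled = panel[panel.columns[::-1]]
        pd.testing.assert_series_equal(o.response_cv(panel),
                                       o.response_cv(shuffled))

    def test_too_few_donors_rejected(self):
        panel = pd.DataFrame([[1.0, 2.0]], index=pd.Index(["g"]),
                             columns=["d1", "d2"])
        with pytest.raises(ValueError, match="3 donors"):
            o.response_cv(panel)

    def test_nonpositive_ratio_names_cell(self):
        panel = pd.DataFrame([[1.0, 0.0, 2.0]], index=pd.Index(["g"]),
                             columns=["d1", "d2", "d3"])
        with pytest.raises(ValueError, match="g.*d2"):
            o.response_cv(panel)


class TestValidation:
    def _var(self, cvs, strata):
        idx = pd.Index([f"g{i}" for i in range(len(cvs))], name="gene_id")
        return pd.DataFrame({"cv": cvs, "stratum": strata}, index=idx)

    def test_identical_response_cv_gives_flat_result(self):
        var = self._var([1.0] * 3 + [0.1] * 3,
                        ["most_variable"] * 3 + ["least_variable"] * 3)
        resp = pd.Series(0.5, index=var.index)
        rep = o.variability_validation(var, resp)
        assert rep.t_stat == pytest.approx(0.0) and rep.t_p == pytest.approx(1.0)

    def test_perfectly_linear_correlation(self):
        cvs = [0.1, 0.2, 0.4, 0.8, 1.2, 1.5]
        var = self._var(cvs, ["middle"] * 6)
        resp = pd.Series([2 * c for c in cvs], index=var.index)
        rep = o.variability_validation(var, resp)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.pearson_p < 1e-6

    def test_coupled_panel_validates(self, spec, cfg, hepatocyte,
                                     general_cohort):
        """Default coupling: significant Welch test and positive correlation."""
        _, _, genes, _ = hepatocyte
        cm, truth = general_cohort
        var = o.population_cv(o.cpm(cm), genes, cfg, "general")
        picks = truth.genes[truth.genes["plant_stratum"].isin(["most", "least"])]
        panel_genes = (picks.index[picks["plant_stratum"] == "most"][:12].tolist()
                       + picks.index[picks["plant_stratum"] == "least"].tolist())
        panel = o.simulate_donor_panel(spec, truth, panel_genes)
        rep = o.variability_validation(var, o.response_cv(panel))
        assert rep.t_stat > 0 and rep.t_p < 0.05
        assert rep.pearson_r > 0 and rep.pearson_p < 0.05
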