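import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import omega3sig as o
from omega3sig import diffexpr
from omega3sig.diffexpr import PHI_FLOOR


def _two_group(counts_a, counts_b, genes=None, libs=None):
    """CountMatrix + DesignTable for a vehicle-vs-DHA layout."""
    counts_a, counts_b = np.atleast_2d(counts_a), np.atleast_2d(counts_b)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    samples = [f"veh{i}" for i in range(n_a)] + [f"dha{i}" for i in range(n_b)]
    genes = genes or [f"g{i}" for i in range(counts_a.shape[0])]
    df = pd.DataFrame(np.hstack([counts_a, counts_b]),
                      index=pd.Index(genes, name="gene_id"), columns=samples)
    ls = pd.Series(libs, index=df.columns) if libs is not None else None
    cm = o.CountMatrix(df, ls)
    design = o.DesignTable(pd.DataFrame({
        "sample_id": samples,
        "condition": ["vehicle"] * n_a + ["DHA"] * n_b,
        "donor_id": "D1",
        "replicate": list(range(n_a)) + list(range(n_b)),
    }))
    return cm, design


def bh_bruteforce(p):
    """Literal step-up: padj_(i) = min_{j>=i}(p_(j) m/j), mapped back."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestDispersion:
    def test_poisson_genes_hit_floor(self):
        rng = np.random.default_rng(0)
        n_genes = 1000
        a = rng.poisson(200, size=(n_genes, 6))
        b = rng.poisson(200, size=(n_genes, 6))
        lib = [1_000_000] * 12
        cm, design = _two_group(a, b, libs=lib)
        phi = diffexpr.estimate_dispersion(
            cm, design, [design.samples_of("vehicle"), design.samples_of("DHA")])
        # the raw moment estimate is symmetric around 0 for Poisson data, so
        # the negative half clips to the floor and the rest stays negligible
        assert np.mean(phi == PHI_FLOOR) >= 0.3
        assert np.mean(phi <= 0.005) >= 0.95
        assert np.median(phi) < 0.002

    def test_planted_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        mu, phi_true, n = 500.0, 0.1, 10
        size = 1.0 / phi_true
        a = rng.negative_binomial(size, size / (size + mu), size=(1000, n))
        b = rng.negative_binomial(size, size / (size + mu), size=(1000, n))
        cm, design = _two_group(a, b, libs=[1_000_000] * (2 * n))
        phi = diffexpr.estimate_dispersion(
            cm, design, [design.samples_of("vehicle"), design.samples_of("DHA")])
        assert 0.05 <= np.median(phi) <= 0.2

    def test_constant_counts_floor(self):
        cm, design = _two_group([[100, 100, 100]], [[100, 100, 100]],
                                libs=[1_000_000] * 6)
        phi = diffexpr.estimate_dispersion(
            cm, design, [design.samples_of("vehicle"), design.samples_of("DHA")])
        assert phi[0] == PHI_FLOOR

    def test_singleton_group_rejected(self):
        cm, design = _two_group([[1, 2]], [[3]])
        with pytest.raises(ValueError, match="2 replicates"):
            diffexpr.estimate_dispersion(cm, design, [["veh0", "veh1"], ["dha0"]])


class TestWald:
    def test_fold_change_recovery_low_bias(self):
        """Group means 100 vs 400 at phi=0.01, n=5: log2FC estimate ~ 2."""
        rng = np.random.default_rng(2)
        size = 1.0 / 0.01
        a = rng.negative_binomial(size, size / (size + 100.0), size=(500, 5))
        b = rng.negative_binomial(size, size / (size + 400.0), size=(500, 5))
        cm, design = _two_group(a, b, libs=[1_000_000] * 10)
        res = diffexpr.nb_wald_test(cm, design, ("DHA", "vehicle"),
                                    phi=np.full(500, 0.01))
        assert abs(res["log2FC"].mean() - 2.0) < 0.1

    def test_all_zero_gene_degenerate(self):
        cm, design = _two_group([[0, 0, 0], [10, 20, 30]],
                                [[0, 0, 0], [10, 20, 30]],
                                libs=[1_000_000] * 6)
        res = diffexpr.nb_wald_test(cm, design, ("DHA", "vehicle"))
        assert res.loc["g0", "p"] == 1.0 and res.loc["g0", "log2FC"] == 0.0
        assert bool(res.loc["g0", "degenerate"])

    def test_label_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(100, size=(50, 4))
        b = rng.poisson(150, size=(50, 4))
        cm, design = _two_group(a, b, libs=[1_000_000] * 8)
        phi = np.full(50, 0.05)
        fwd = diffexpr.nb_wald_test(cm, design, ("DHA", "vehicle"), phi=phi)
        rev = diffexpr.nb_wald_test(cm, design, ("vehicle", "DHA"), phi=phi)
        np.testing.assert_allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-6)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-8)


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(o.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_one(self):
        assert o.bh_adjust([1.0]).tolist() == [1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            o.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(deadline=None, max_examples=200)
    def test_matches_bruteforce_stepup(self, p):
        np.testing.assert_allclose(o.bh_adjust(p), bh_bruteforce(p), atol=1e-12)
        adj = o.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()


class TestCalls:
    @pytest.fixture
    def genes(self):
        return o.GeneTable.from_records(
            ["cod", "lnc"], ["protein_coding", "lncRNA"])

    def _results(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_threshold_is_strict(self, genes, cfg):
        res = self._results([
            {"gene_id": "cod", "log2FC": 0.2, "p": 0.001, "padj": 0.01},
            {"gene_id": "lnc", "log2FC": 0.18, "p": 0.001, "padj": 0.01},
        ])
        out = o.call_de(res, genes, cfg)
        assert out.loc["cod", "call"] == "ns"   # 0.2 is not > 0.2
        assert out.loc["lnc", "call"] == "up"   # 0.18 > 0.15

    def test_alpha_gate(self, genes, cfg):
        res = self._results([
            {"gene_id": "cod", "log2FC": 1.5, "p": 0.03, "padj": 0.06}])
        assert o.call_de(res, genes, cfg).loc["cod", "call"] == "ns"

    def test_unknown_gene_rejected(self, genes, cfg):
        res = self._results([
            {"gene_id": "mystery", "log2FC": 1.0, "p": 0.001, "padj": 0.001}])
        with pytest.raises(ValueError, match="mystery"):
            o.call_de(res, genes, cfg)


class TestTechnicalReplicates:
    def test_sum_preserves_totals(self, hepatocyte):
        cm, design, _, _ = hepatocyte
        doubled = o.DesignTable(pd.concat(
            [design.table.assign(sample_id=design.table.sample_id)],
            ignore_index=True))
        merged, new_design = diffexpr.combine_technical_replicates(cm, design)
        assert merged.counts.values.sum() == cm.counts.values.sum()
        assert len(new_design) == len(design)

    def test_two_lanes_summed(self):
        cm, design = _two_group([[1, 2]], [[3, 4]])
        lanes = o.DesignTable(pd.DataFrame({
            "sample_id": ["veh0", "veh1", "dha0", "dha1"],
            "condition": ["vehicle", "vehicle", "DHA", "DHA"],
            "donor_id": "D1",
            "replicate": [1, 1, 1, 1],
        }))
        merged, md = diffexpr.combine_technical_replicates(cm, lanes)
        assert merged.counts.iloc[0].tolist() == [3, 7]
        assert len(md) == 2
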