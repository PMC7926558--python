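import numpy as np
import pandas as pd
import pytest

import omega3sig as o


@pytest.fixture(scope="session")
def cfg():
    return o.RunConfig(rng_seed=1)


@pytest.fixture(scope="session")
def spec():
    return o.SimSpec(rng_seed=1)


@pytest.fixture(scope="session")
def hepatocyte(spec):
    """Default simulated hepatocyte experiment (counts, design, genes, truth)."""
    return o.simulate_hepatocyte_experiment(spec)


@pytest.fixture(scope="session")
def general_cohort(spec):
    return o.simulate_population_cohort(spec, "general")


@pytest.fixture(scope="session")
def disease_cohort(spec):
    return o.simulate_population_cohort(spec, "disease")


@pytest.fixture(scope="session")
def de_results(hepatocyte, cfg):
    """Called DE tables for the three contrasts on the expressed universe."""
    cm, design, genes, truth = hepatocyte
    universe = o.filter_expressed(o.cpm(cm), genes, cfg)
    return {
        cond: o.de_contrast(cm, design, cond, genes, cfg, universe=universe)
        for cond in ("DHA", "EPA", "OA")
    }


@pytest.fixture
def tiny_counts():
    """3 genes x 2 samples with known column sums (15, 105)."""
    df = pd.DataFrame(
        [[10, 0], [5, 5], [0, 100]],
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        columns=["s1", "s2"],
    )
    return o.CountMatrix(df)


def truth_calls(truth_genes: pd.DataFrame) -> dict:
    """Ground-truth DE tables (perfect calls) for the set-algebra oracle."""
    out = {}
    for cond in ("DHA", "EPA", "OA"):
        lfc = truth_genes[f"lfc_{cond}"]
        call = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "ns"))
        out[cond] = pd.DataFrame(
            {"call": call, "log2FC": lfc}, index=truth_genes.index)
    return out
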