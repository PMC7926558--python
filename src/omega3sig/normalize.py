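"""CPM normalisation, biotype-aware expression filtering, log transform, PCA.

CPM (counts per million) is the working expression unit: a gene is called
expressed when its CPM reaches the biotype-specific threshold (1 for
protein-coding, 0.5 for lncRNA) in at least half of the samples. Exactly
half counts as retained, and a CPM exactly at the threshold passes (the
exclusion rule drops genes strictly below threshold). For sample overview,
counts are variance-flattened as log2(CPM + 1) before PCA — any monotone
flattening transform serves the visual clustering purpose here.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import RunConfig
from .io import CountMatrix, DesignTable, GeneTable

logger = logging.getLogger("omega3sig")

__all__ = ["ExpressionMatrix", "cpm", "filter_expressed", "vst",
           "pca_overview", "remove_shallow_samples"]


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples real-valued matrix tagged with its scale."""

    values: pd.DataFrame
    scale: str  # "cpm" | "log2cpm"

    def __post_init__(self) -> None:
        if self.scale not in ("cpm", "log2cpm"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        v = self.values.to_numpy()
        if not np.isfinite(v).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "cpm" and (v < 0).any():
            raise ValueError("CPM values must be >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.scale)


def remove_shallow_samples(cm: CountMatrix, min_reads: int = 1_000_000) -> CountMatrix:
    """Drop outlier samples with fewer aligned reads than ``min_reads``.

    Applied before CPM so shallow outliers cannot distort filtering.
    """
    keep = cm.library_size[cm.library_size >= min_reads].index
    dropped = cm.n_samples - len(keep)
    if dropped:
        logger.warning("removed %d shallow sample(s) below %d reads", dropped, min_reads)
    if len(keep) == 0:
        raise ValueError("all samples fall below the read-depth floor")
    return cm.subset_samples(keep)


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count / library_size * 1e6."""
    ls = counts.library_size
    if (ls <= 0).any():
        bad = ls.index[ls <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    vals = counts.counts.div(ls, axis=1) * 1e6
    return ExpressionMatrix(vals, "cpm")


def filter_expressed(
    expr: ExpressionMatrix, genes: GeneTable, cfg: RunConfig
) -> list[str]:
    """Gene ids passing the biotype-specific CPM expression filter.

    Retained iff CPM >= threshold in at least ceil(frac_samples * n_samples)
    samples; input gene order is preserved.
    """
    if expr.scale != "cpm":
        raise ValueError(f"expression filter requires CPM scale, got {expr.scale!r}")
    n_required = math.ceil(cfg.frac_samples * len(expr.sample_ids))
    biotypes = genes.biotype_of(expr.gene_ids)
    thr = np.where(biotypes.to_numpy() == "lncRNA", cfg.cpm_lnc, cfg.cpm_coding)
    n_pass = (expr.values.to_numpy() >= thr[:, None]).sum(axis=1)
    retained = expr.gene_ids[n_pass >= n_required].tolist()
    logger.info("expression filter: %d of %d genes retained",
                len(retained), len(expr.gene_ids))
    return retained


def vst(counts: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Variance-flattening transform log2(CPM + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c = cpm(counts)
    return ExpressionMatrix(np.log2(c.values + pseudocount), "log2cpm")


def pca_overview(
    expr: ExpressionMatrix, design: DesignTable | None = None, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA of a log-scale expression matrix.

    Genes are mean-centred; samples are the observations. Returns per-sample
    component scores (joined with the condition labels when a design is
    given) and the explained-variance fractions, which are non-increasing
    and sum to at most 1.
    """
    if expr.scale != "log2cpm":
        raise ValueError("PCA expects a log2cpm-scale matrix")
    n_samples = len(expr.sample_ids)
    if n_samples < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples for "
                         f"{n_components} components")
    X = expr.values.to_numpy().T  # samples x genes
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("expression matrix is constant; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    out = pd.DataFrame(
        scores,
        index=pd.Index(expr.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    if design is not None:
        cond = design.table.set_index("sample_id")["condition"]
        out = out.join(cond)
    return out, pca.explained_variance_ratio_
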