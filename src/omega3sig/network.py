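"""lncRNA-mRNA co-expression networks and per-lncRNA gene-set enrichment.

Signature lncRNAs are functionally profiled by guilt-by-association: each
lncRNA is correlated (Pearson) with every expressed protein-coding gene
across a population cohort, edges are kept at |r| > 0.6 and p < 0.05, and
the coding genes connected to a lncRNA are tested for over-representation in
user-supplied gene sets (one-sided hypergeometric, BH-adjusted within each
lncRNA). Pathways significant for many lncRNAs of a group are aggregated
into top-k representative pathways by support count.
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .diffexpr import bh_adjust
from .io import GeneSetCollection
from .normalize import ExpressionMatrix

logger = logging.getLogger("omega3sig")

__all__ = ["correlate_lnc_mrna", "network_components", "enrich_per_lnc",
           "representative_pathways", "pearson_p"]


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r at sample size n: t = r sqrt(n-2)/sqrt(1-r^2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def correlate_lnc_mrna(
    expr: ExpressionMatrix,
    lnc_ids: Sequence[str],
    mrna_ids: Sequence[str],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Retained lncRNA-mRNA correlation edges over a population cohort.

    Pearson r for every (lncRNA, coding) pair; an edge is kept when
    |r| > cfg.corr_r (strict) and p < cfg.corr_p. Zero-variance genes are
    skipped with a warning. Needs >= 4 samples.
    """
    n = len(expr.sample_ids)
    if n < 4:
        raise ValueError("correlation needs >= 4 samples")
    lnc_ids = [g for g in lnc_ids if g not in set(mrna_ids)]
    X = expr.values.loc[list(lnc_ids)].to_numpy(dtype=float)
    Y = expr.values.loc[list(mrna_ids)].to_numpy(dtype=float)

    def _standardise(M, ids):
        sd = M.std(axis=1, ddof=1)
        keep = sd > 0
        if (~keep).any():
            logger.warning("%d zero-variance gene(s) skipped in correlation",
                           int((~keep).sum()))
        Z = (M[keep] - M[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return Z, [g for g, k in zip(ids, keep) if k]

    Zx, lnc_kept = _standardise(X, list(lnc_ids))
    Zy, mrna_kept = _standardise(Y, list(mrna_ids))
    if not len(lnc_kept) or not len(mrna_kept):
        return pd.DataFrame(columns=["lnc_id", "mrna_id", "r", "p"])
    R = (Zx @ Zy.T) / (n - 1)
    P = pearson_p(R, n)
    li, mi = np.nonzero((np.abs(R) > cfg.corr_r) & (P < cfg.corr_p))
    edges = pd.DataFrame({
        "lnc_id": np.asarray(lnc_kept, dtype=object)[li],
        "mrna_id": np.asarray(mrna_kept, dtype=object)[mi],
        "r": R[li, mi],
        "p": P[li, mi],
    })
    logger.info("correlation network: %d edges (%d lncRNA x %d coding)",
                len(edges), len(lnc_kept), len(mrna_kept))
    return edges.sort_values(["lnc_id", "mrna_id"]).reset_index(drop=True)


def network_components(edges: pd.DataFrame) -> tuple[list[set[str]], pd.DataFrame]:
    """Connected components and per-lncRNA degree of the bipartite graph."""
    g = nx.Graph()
    for lnc, mrna in zip(edges["lnc_id"], edges["mrna_id"]):
        g.add_edge(("lnc", lnc), ("mrna", mrna))
    comps = [
        {name for (_, name) in comp}
        for comp in nx.connected_components(g)
    ]
    lnc_nodes = [node for node in g.nodes if node[0] == "lnc"]
    degree = pd.DataFrame(
        {"lnc_id": [name for (_, name) in lnc_nodes],
         "degree": [g.degree[node] for node in lnc_nodes]}
    ).sort_values(["degree", "lnc_id"], ascending=[False, True]).reset_index(drop=True)
    return comps, degree


def enrich_per_lnc(
    edges: pd.DataFrame,
    gene_sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each lncRNA's correlated mRNAs.

    For each lncRNA, the query is its connected coding genes; for each gene
    set (intersected with the universe), p = P(X >= overlap) under sampling
    without replacement; BH adjustment is applied across sets within each
    lncRNA. Sets entirely outside the universe are skipped with a warning.
    """
    universe_set = set(universe)
    rows = []
    trimmed_sets = {}
    for name in gene_sets.names():
        members = [g for g in gene_sets[name] if g in universe_set]
        if not members:
            logger.warning("gene set %r entirely outside the universe; skipped", name)
            continue
        trimmed_sets[name] = set(members)
    M = len(universe_set)
    for lnc, grp in edges.groupby("lnc_id", sort=True):
        query = set(grp["mrna_id"]) & universe_set
        if not query:
            continue
        N = len(query)
        recs = []
        for name, members in trimmed_sets.items():
            K = len(members)
            k = len(members & query)
            p = float(stats.hypergeom.sf(k - 1, M, K, N))
            recs.append({"lnc_id": lnc, "set_name": name, "overlap": k,
                         "set_size": K, "query_size": N, "universe_size": M,
                         "p": min(p, 1.0)})
        if not recs:
            continue
        sub = pd.DataFrame(recs)
        sub["padj"] = bh_adjust(sub["p"].to_numpy())
        rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["lnc_id", "set_name", "overlap", "set_size",
                                     "query_size", "universe_size", "p", "padj"])
    return pd.concat(rows, ignore_index=True)


def representative_pathways(
    records: pd.DataFrame,
    group: Sequence[str],
    k: int = 5,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Top-k pathways by how many group lncRNAs find them significant.

    Support = number of lncRNAs in ``group`` with p < alpha (nominal by
    default; ``use_adjusted`` switches to BH-adjusted) for the pathway.
    Ranked by support (desc), then ascending median significant p, then
    name; no padding when fewer than k pathways qualify.
    """
    group_set = set(group)
    if not group_set:
        return pd.DataFrame(columns=["set_name", "support", "median_p"])
    col = "padj" if use_adjusted else "p"
    sig = records[records["lnc_id"].isin(group_set) & (records[col] < alpha)]
    if sig.empty:
        return pd.DataFrame(columns=["set_name", "support", "median_p"])
    agg = sig.groupby("set_name").agg(
        support=("lnc_id", "nunique"), median_p=(col, "median")).reset_index()
    agg = agg.sort_values(["support", "median_p", "set_name"],
                          ascending=[False, True, True]).reset_index(drop=True)
    return agg.head(k)
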