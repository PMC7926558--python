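"""Population expression variability, donor response variability, validation.

The coefficient of variation (CV = sd/mean, n-1 sd, computed on the CPM
scale) quantifies across-individual expression variability within a cohort.
Genes are stratified into the most-variable (top quantile of CV) and
least-variable (bottom quantile) strata; the quantile width defaults to a
quartile. A gene counts as most (least) variable *overall* only when it
falls in that stratum in both the general and the disease cohort.

Response variability is the CV of treatment/vehicle expression ratios
across a donor panel. The validation stage tests the central premise that
population expression variability predicts response variability: a Welch
t-test comparing response CV between the most- and least-variable strata,
and a Pearson correlation between population CV and response CV.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import GeneTable
from .normalize import ExpressionMatrix, filter_expressed

logger = logging.getLogger("omega3sig")

__all__ = ["population_cv", "stratify", "stratified_signature_intersection",
           "response_cv", "variability_validation", "ValidationReport"]


def _cv(values: np.ndarray, axis: int = 1) -> np.ndarray:
    m = values.mean(axis=axis)
    s = values.std(axis=axis, ddof=1)
    return s / np.maximum(m, 1e-300)


def population_cv(
    expr: ExpressionMatrix, genes: GeneTable, cfg: RunConfig, cohort: str
) -> pd.DataFrame:
    """Per-gene CV across a population cohort, with quantile strata.

    Only genes passing the cohort expression filter enter; the returned
    frame has mean_cpm, cv, stratum and the cohort label.
    """
    if expr.scale != "cpm":
        raise ValueError("population CV is computed on the CPM scale")
    retained = filter_expressed(expr, genes, cfg)
    sub = expr.values.loc[retained]
    vals = sub.to_numpy()
    mean = vals.mean(axis=1)
    if (mean <= 0).any():
        raise AssertionError("zero-mean gene survived the expression filter")
    table = pd.DataFrame(
        {"cohort": cohort, "mean_cpm": mean, "cv": _cv(vals)},
        index=sub.index,
    )
    table["stratum"] = stratify(table["cv"], cfg.quantile)
    return table


def stratify(cv: pd.Series, quantile: float) -> pd.Series:
    """Assign most/least/middle strata of width ``quantile``.

    Stratum sizes are exactly floor(quantile * n); boundary ties are broken
    by ascending gene_id for determinism.
    """
    n_sel = math.floor(quantile * len(cv))
    ordered = cv.to_frame("cv").reset_index()
    idcol = ordered.columns[0]
    ordered = ordered.sort_values(["cv", idcol], ascending=[True, True])
    ids = ordered[idcol].to_numpy()
    strata = pd.Series("middle", index=cv.index, name="stratum")
    strata[ids[:n_sel]] = "least_variable"
    strata[ids[len(cv) - n_sel:]] = "most_variable"
    return strata


def stratified_signature_intersection(
    variability: Mapping[str, pd.DataFrame],
    assignments: pd.DataFrame,
    signature_classes: Sequence[str] = ("DHA_only", "EPA_only", "DHA_and_EPA"),
) -> pd.DataFrame:
    """Intersect signature classes with cross-cohort variability strata.

    ``variability`` maps cohort name -> population_cv frame. A gene is most
    (least) variable overall iff it is so in every cohort supplied. Returns
    per-class counts of most/least variable members, their gene lists and
    the most/least ratio.
    """
    cohorts = list(variability)
    if not cohorts:
        raise ValueError("no variability tables supplied")
    shared = None
    for c in cohorts:
        ids = set(variability[c].index)
        shared = ids if shared is None else (shared & ids)
    if not shared:
        raise ValueError("variability tables have disjoint gene universes")

    def overall(stratum: str) -> set[str]:
        sets = [set(v.index[v["stratum"] == stratum]) for v in variability.values()]
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out

    most, least = overall("most_variable"), overall("least_variable")
    rows = []
    for cls in signature_classes:
        members = set(assignments.index[assignments["signature_class"] == cls])
        m = sorted(members & most)
        l = sorted(members & least)
        ratio = len(m) / len(l) if l else float("inf") if m else float("nan")
        rows.append({"signature_class": cls, "n_most_variable": len(m),
                     "n_least_variable": len(l), "ratio_most_to_least": ratio,
                     "most_variable_genes": ",".join(m),
                     "least_variable_genes": ",".join(l)})
    return pd.DataFrame(rows)


def response_cv(panel: pd.DataFrame) -> pd.Series:
    """CV of treatment/vehicle ratios across donors, per gene.

    ``panel`` is genes x donors with strictly positive ratios; at least
    three donors are required.
    """
    if panel.shape[1] < 3:
        raise ValueError("response CV needs >= 3 donors")
    vals = panel.to_numpy(dtype=float)
    bad = ~(vals > 0)
    if bad.any():
        g, d = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive ratio at gene {panel.index[g]!r}, donor {panel.columns[d]!r}")
    return pd.Series(_cv(vals), index=panel.index, name="response_cv")


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    """Fig-4-style validation: stratum comparison plus CV-CV correlation."""

    t_stat: float
    t_p: float
    n_most: int
    n_least: int
    pearson_r: float
    pearson_p: float
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"comparison": "response_cv_most_vs_least", "statistic": self.t_stat,
             "p": self.t_p, "n": self.n_most + self.n_least},
            {"comparison": "population_cv_vs_response_cv", "statistic": self.pearson_r,
             "p": self.pearson_p, "n": self.n_genes},
        ])


def variability_validation(
    var_table: pd.DataFrame,
    resp_cv: pd.Series,
    equal_var: bool = False,
) -> ValidationReport:
    """Test whether population CV predicts donor response CV.

    Welch two-sided t-test (Student's by ``equal_var=True``) compares the
    response CV of most- vs least-variable genes; Pearson correlation (with
    t-distribution p, df = n-2) relates population CV to response CV over
    all genes present in both tables. Needs >= 3 genes per stratum and
    >= 3 paired genes.
    """
    common = var_table.index.intersection(resp_cv.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes shared between variability and response")
    v = var_table.loc[common]
    r = resp_cv.loc[common]
    most = r[v["stratum"] == "most_variable"]
    least = r[v["stratum"] == "least_variable"]
    if len(most) >= 3 and len(least) >= 3:
        t_stat, t_p = stats.ttest_ind(most, least, equal_var=equal_var)
        if np.isnan(t_stat) and np.isclose(most.mean(), least.mean()):
            t_stat, t_p = 0.0, 1.0  # both strata constant and equal
    else:
        logger.warning("a stratum has < 3 genes; group test skipped")
        t_stat, t_p = float("nan"), float("nan")
    pr = stats.pearsonr(v["cv"].to_numpy(), r.to_numpy())
    return ValidationReport(
        t_stat=float(t_stat), t_p=float(t_p),
        n_most=len(most), n_least=len(least),
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        n_genes=len(common),
    )
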