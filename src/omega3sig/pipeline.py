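"""End-to-end roadmap: from input cohorts to exosome-detectable biomarkers.

Stage order: expression filtering -> DE (three contrasts vs vehicle) ->
OA-subtracted signature classes -> population CV in two cohorts ->
cross-cohort stratified intersection -> donor-panel response-CV validation
-> lncRNA network + enrichment -> exosome origin partitioning and
detectability -> final biomarker intersection. Every stage output is
written as TSV next to a resolved copy of the configuration; the whole run
is a pure function of (config, simulation spec), so a rerun under the same
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import diffexpr, exosome, network, signatures, variability
from .config import RunConfig, write_config
from .io import (FLOAT_FORMAT, CountMatrix, DesignTable, GeneSetCollection,
                 GeneTable, write_count_matrix, write_design_table,
                 write_gene_table)
from .normalize import cpm, filter_expressed, pca_overview, vst
from .simulate import (GroundTruth, SimSpec, simulate_donor_panel,
                       simulate_exosome_reads, simulate_gene_sets,
                       simulate_hepatocyte_experiment,
                       simulate_population_cohort, with_mouse_genes)

logger = logging.getLogger("omega3sig")

__all__ = ["RoadmapReport", "RoadmapInputs", "simulate_inputs", "run_roadmap",
           "make_report"]


@dataclasses.dataclass
class RoadmapInputs:
    """Everything the roadmap consumes, real or simulated."""

    counts: CountMatrix
    design: DesignTable
    genes: GeneTable
    population: Mapping[str, CountMatrix]      # cohort -> matrix
    gene_sets: GeneSetCollection | None = None
    exosome_records: pd.DataFrame | None = None
    combined_genes: GeneTable | None = None    # human + mouse, for exosome stage
    truth: GroundTruth | None = None
    spec: SimSpec | None = None


@dataclasses.dataclass
class RoadmapReport:
    """Collected stage outputs plus the provenance to reproduce them."""

    config: RunConfig
    pca_scores: pd.DataFrame
    pca_explained: list[float]
    de: Mapping[str, pd.DataFrame]
    assignments: pd.DataFrame
    composition: pd.DataFrame
    variability: Mapping[str, pd.DataFrame]
    stratified: pd.DataFrame
    validation: variability.ValidationReport | None
    edges: pd.DataFrame
    enrichment: pd.DataFrame
    representative: pd.DataFrame
    exo_counts: pd.Series
    detectable: list[str]
    biomarkers: pd.DataFrame
    n_expressed: int
    panel_treatment: str = "DHA"

    def summary_lines(self) -> list[str]:
        lines = [
            "roadmap summary",
            f"seed: {self.config.rng_seed}",
            f"expressed genes: {self.n_expressed}",
        ]
        for cond, res in sorted(self.de.items()):
            up = int((res["call"] == "up").sum())
            down = int((res["call"] == "down").sum())
            lines.append(f"DE {cond} vs vehicle: {up} up, {down} down")
        counts = self.assignments["signature_class"].value_counts()
        for cls in signatures.SIGNATURE_CLASSES:
            lines.append(f"signature {cls}: {int(counts.get(cls, 0))}")
        for _, row in self.stratified.iterrows():
            lines.append(
                f"stratified {row['signature_class']}: "
                f"{row['n_most_variable']} most / {row['n_least_variable']} least variable")
        if self.validation is not None:
            v = self.validation
            lines.append(
                f"validation: welch t={v.t_stat:.4g} p={v.t_p:.4g} "
                f"(n={v.n_most}+{v.n_least}); pearson r={v.pearson_r:.4g} "
                f"p={v.pearson_p:.4g} (n={v.n_genes})")
            if not (v.t_p < 0.05 and v.pearson_p < 0.05 and v.pearson_r > 0):
                lines.append("validation: NOT significant — population CV does not "
                             "predict response CV in this run")
        lines.append(f"network edges: {len(self.edges)}")
        lines.append(f"exosome-detectable genes: {len(self.detectable)}")
        for _, row in self.biomarkers.iterrows():
            lines.append(
                f"biomarkers {row['signature_class']}: {row['n_detected']} of "
                f"{row['n_signature']} most-variable signature genes detectable")
        return lines


def simulate_inputs(spec: SimSpec) -> RoadmapInputs:
    """Generate every roadmap input cohort from one simulation spec."""
    counts, design, genes, truth = simulate_hepatocyte_experiment(spec)
    population = {}
    for cohort in ("general", "disease"):
        cm, _ = simulate_population_cohort(spec, cohort)
        population[cohort] = cm
    combined = with_mouse_genes(genes, spec.n_mouse_genes)
    # plant the most-variable signature genes into the exosome top quintile so
    # the final intersection has known content
    boost = truth.genes.index[truth.genes["plant_stratum"] == "most"].tolist()
    records, exo_truth = simulate_exosome_reads(spec, combined, boost_genes=boost)
    truth = GroundTruth(
        genes=truth.genes.join(exo_truth.genes, how="left"),
        reads=exo_truth.reads,
    )
    tg = truth.genes
    modules = {
        int(m): tg.index[(tg["module"] == m) & (tg["biotype"] == "protein_coding")]
        .tolist()
        for m in sorted(tg.loc[tg["module"] >= 0, "module"].unique())
    }
    gene_sets = simulate_gene_sets(
        spec, genes.genes_of_biotype("protein_coding"), modules=modules)
    return RoadmapInputs(counts=counts, design=design, genes=genes,
                         population=population, gene_sets=gene_sets,
                         exosome_records=records, combined_genes=combined,
                         truth=truth, spec=spec)


def run_roadmap(
    cfg: RunConfig,
    inputs: RoadmapInputs | None = None,
    out_dir: str | Path | None = None,
    panel_treatment: str = "DHA",
) -> RoadmapReport:
    """Execute every stage of the biomarker-selection roadmap.

    With no ``inputs``, cohorts are simulated from a default spec seeded by
    ``cfg.rng_seed``. When ``out_dir`` is given, all stage TSVs, the summary
    and the resolved config are written there.
    """
    if inputs is None:
        inputs = simulate_inputs(SimSpec(rng_seed=cfg.rng_seed))

    # 1. normalisation and expression filter
    expr = cpm(inputs.counts)
    universe = filter_expressed(expr, inputs.genes, cfg)
    n_expressed = len(universe)
    logger.info("stage normalize: %d expressed of %d genes",
                n_expressed, inputs.counts.n_genes)
    scores, evr = pca_overview(vst(inputs.counts), inputs.design)

    # 2. differential expression, three contrasts on the expressed universe
    de = {cond: diffexpr.de_contrast(inputs.counts, inputs.design, cond,
                                     inputs.genes, cfg, universe=universe)
          for cond in ("DHA", "EPA", "OA")}

    # 3. signature set algebra
    assignments = signatures.assign_signatures(de, inputs.genes)
    composition = signatures.composition_summary(assignments)

    # 4. population variability per cohort
    var_tables = {}
    for cohort, cm in inputs.population.items():
        var_tables[cohort] = variability.population_cv(
            cpm(cm), inputs.genes, cfg, cohort)

    # 5. cross-cohort stratified intersection with the signature classes
    stratified = variability.stratified_signature_intersection(
        var_tables, assignments)

    # 6. donor-panel validation on most+least variable signature genes
    validation = None
    panel_genes: list[str] = []
    for _, row in stratified.iterrows():
        for col in ("most_variable_genes", "least_variable_genes"):
            panel_genes += [g for g in row[col].split(",") if g]
    panel_genes = sorted(set(panel_genes))
    if inputs.truth is not None and inputs.spec is not None and len(panel_genes) >= 6:
        panel = simulate_donor_panel(inputs.spec, inputs.truth, panel_genes,
                                     treatment=panel_treatment)
        resp = variability.response_cv(panel)
        validation = variability.variability_validation(
            var_tables["general"], resp)

    # 7. lncRNA network + enrichment over the general cohort
    sig_mask = assignments["signature_class"].isin(
        ("DHA_only", "EPA_only", "DHA_and_EPA"))
    lnc_ids = [g for g in assignments.index[
        sig_mask & (assignments["biotype"] == "lncRNA")]]
    pop_expr = cpm(inputs.population["general"])
    pop_universe = set(var_tables["general"].index)
    coding = [g for g in pop_universe
              if inputs.genes.table.loc[g, "biotype"] == "protein_coding"]
    lnc_expressed = [g for g in lnc_ids if g in pop_universe]
    edges = network.correlate_lnc_mrna(
        pop_expr.subset_genes(sorted(set(lnc_expressed) | set(coding))),
        lnc_expressed, sorted(coding), cfg)
    if inputs.gene_sets is not None and len(edges):
        enrichment = network.enrich_per_lnc(edges, inputs.gene_sets, sorted(coding))
        representative = network.representative_pathways(
            enrichment, lnc_expressed, k=5, alpha=cfg.alpha)
    else:
        enrichment = pd.DataFrame(columns=["lnc_id", "set_name", "overlap", "p", "padj"])
        representative = pd.DataFrame(columns=["set_name", "support", "median_p"])

    # 8. exosome origin partitioning + detectability filter
    if inputs.exosome_records is not None and inputs.combined_genes is not None:
        origins = exosome.assign_origin(inputs.exosome_records)
        exo_counts = exosome.quantify_human_genes(origins, inputs.combined_genes)
        detectable = exosome.top_fraction(exo_counts, cfg.exo_top_frac)
    else:
        exo_counts = pd.Series(dtype=float)
        detectable = []

    # 9. final biomarker intersection
    most_var = {
        row["signature_class"]: [g for g in row["most_variable_genes"].split(",") if g]
        for _, row in stratified.iterrows()
    }
    biomarkers = exosome.biomarker_intersection(detectable, most_var)

    report = RoadmapReport(
        config=cfg, pca_scores=scores, pca_explained=[float(x) for x in evr],
        de=de, assignments=assignments, composition=composition,
        variability=var_tables, stratified=stratified, validation=validation,
        edges=edges, enrichment=enrichment, representative=representative,
        exo_counts=exo_counts, detectable=detectable, biomarkers=biomarkers,
        n_expressed=n_expressed, panel_treatment=panel_treatment,
    )
    if out_dir is not None:
        make_report(report, inputs, Path(out_dir))
    return report


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def make_report(report: RoadmapReport, inputs: RoadmapInputs, out_dir: Path) -> None:
    """Write every stage output, the summary and the resolved config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_config(report.config, out_dir / "config.resolved.yaml")
    write_count_matrix(inputs.counts, out_dir / "hepatocyte_counts.tsv")
    write_design_table(inputs.design, out_dir / "design.tsv")
    write_gene_table(inputs.genes, out_dir / "genes.tsv")
    _write(report.pca_scores, out_dir / "pca_scores.tsv")
    for cond, res in report.de.items():
        _write(res, out_dir / f"de_{cond}_vs_vehicle.tsv")
    _write(report.assignments, out_dir / "signature_assignments.tsv")
    _write(report.composition, out_dir / "signature_composition.tsv", index=False)
    _write(signatures.upset_matrix(report.assignments),
           out_dir / "signature_upset.tsv", index=False)
    for cohort, table in report.variability.items():
        _write(table, out_dir / f"variability_{cohort}.tsv")
    _write(report.stratified, out_dir / "stratified_intersection.tsv", index=False)
    if report.validation is not None:
        _write(report.validation.to_frame(), out_dir / "validation.tsv", index=False)
    _write(report.edges, out_dir / "network_edges.tsv", index=False)
    _write(report.enrichment, out_dir / "enrichment.tsv", index=False)
    _write(report.representative, out_dir / "representative_pathways.tsv", index=False)
    _write(report.exo_counts.to_frame("reads"), out_dir / "exosome_gene_counts.tsv")
    (out_dir / "detectable_genes.txt").write_text(
        "\n".join(report.detectable) + "\n" if report.detectable else "")
    _write(report.biomarkers, out_dir / "biomarkers.tsv", index=False)
    (out_dir / "summary.txt").write_text("\n".join(report.summary_lines()) + "\n")
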