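"""Synthetic cohorts with planted ground truth for every pipeline input.

Four generators emulate the four data sources the analysis consumes:

* a treated primary-hepatocyte experiment (vehicle / DHA / EPA / OA,
  negative-binomial counts with planted condition-specific fold changes,
  arranged so every region of the three-way DHA/EPA/OA Venn diagram is
  populated),
* population expression cohorts (a large "general" cohort and a smaller
  fatty-liver "disease" cohort) with planted per-gene coefficients of
  variation,
* a 10-donor treatment/vehicle fold-change panel whose donor-level variance
  is coupled to the planted population CV (coupling coefficient kappa), and
* an exosomal RNA-seq alignment table against a combined human+mouse
  reference with prefixed contigs, mixing human, mouse and ambiguous reads.

All generators draw from a shared per-seed gene universe, so gene ids,
biotypes, baseline means and planted variability are mutually consistent
across cohorts. Every output is a pure function of (spec, spec.rng_seed).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, DesignTable, GeneSetCollection, GeneTable

__all__ = ["SimSpec", "GroundTruth", "simulate_hepatocyte_experiment",
           "simulate_population_cohort", "simulate_donor_panel",
           "simulate_exosome_reads", "simulate_gene_sets", "with_mouse_genes"]

# independent, order-stable RNG streams per generator
_STREAMS = {"universe": 0, "hepatocyte": 1, "general": 2, "disease": 3,
            "donors": 4, "exosome": 5, "genesets": 6}

_VENN_CLASSES = ("DHA", "EPA", "OA", "DHA_EPA", "DHA_OA", "EPA_OA", "DHA_EPA_OA")

_SIGNATURE_OF_VENN = {
    "DHA": "DHA_only", "EPA": "EPA_only", "DHA_EPA": "DHA_and_EPA",
    "DHA_OA": "OA_shared", "EPA_OA": "OA_shared", "DHA_EPA_OA": "OA_shared",
    "OA": "non_responsive", "none": "non_responsive",
}


def _default_venn_quotas() -> dict[str, int]:
    return {"DHA": 60, "EPA": 60, "OA": 40, "DHA_EPA": 80,
            "DHA_OA": 30, "EPA_OA": 30, "DHA_EPA_OA": 40}


def _default_strata_plants() -> dict[str, tuple[int, int]]:
    # (most, least) quotas per signature class; ratios 12x / 7x / 4x
    return {"DHA_and_EPA": (36, 3), "DHA_only": (28, 4), "EPA_only": (24, 6)}


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic study.

    Baseline gene means are log-normal on the count scale at a nominal depth
    of one million reads; negative-binomial dispersion follows the common
    mean-dependent trend ``phi = a0 + a1/mu``. Planted fold-change magnitudes
    are |N(lfc_mean, lfc_sd)| truncated below at ``lfc_min``, signed up or
    down with probability ``up_fraction``. Population CVs span
    ``[cv_min, cv_max]`` log-uniformly, with selected signature genes planted
    into the extreme strata per ``strata_plants``. Donor-panel log-ratio
    variance is ``donor_base_var + kappa * cv**2``.
    """

    n_genes: int = 2000
    frac_lnc: float = 0.2
    frac_silent: float = 0.15
    n_reps: int = 5
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.2
    silent_log_mean: float = -1.0
    silent_log_sd: float = 1.0
    disp_a0: float = 0.02
    disp_a1: float = 2.0
    venn_quotas: Mapping[str, int] = dataclasses.field(default_factory=_default_venn_quotas)
    lfc_mean: float = 1.0
    lfc_sd: float = 0.4
    lfc_min: float = 0.25
    up_fraction: float = 0.5
    lib_log_mean: float = math.log(1e6)
    lib_log_sd: float = 0.15
    # population cohorts
    n_general: int = 100
    n_disease: int = 60
    cv_min: float = 0.05
    cv_max: float = 1.5
    strata_plants: Mapping[str, tuple[int, int]] = dataclasses.field(
        default_factory=_default_strata_plants)
    cv_plant_most: tuple[float, float] = (1.1, 1.5)
    cv_plant_least: tuple[float, float] = (0.05, 0.065)
    cv_plant_mid: tuple[float, float] = (0.25, 0.5)
    disease_cv_jitter: float = 0.08
    # co-expression modules (lncRNA hubs + correlated coding genes)
    n_modules: int = 6
    module_n_lnc: int = 2
    module_n_coding: int = 20
    module_rho: float = 0.85
    module_neg_frac: float = 0.3
    disease_shift_frac: float = 0.3
    disease_shift_sd: float = 0.5
    # donor panel
    n_donors: int = 10
    kappa: float = 0.15
    donor_base_var: float = 0.01
    # exosome read mix
    n_mouse_genes: int = 400
    n_human_reads: int = 50_000
    n_mouse_reads: int = 20_000
    n_ambiguous: int = 1_000
    exo_top_frac: float = 0.2
    mouse_secondary_frac: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for key in ("frac_lnc", "up_fraction", "exo_top_frac", "mouse_secondary_frac",
                    "disease_shift_frac"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{key} must lie in [0, 1], got {v}")
        if self.disp_a0 <= 0 or self.disp_a1 < 0:
            raise ValueError("dispersion coefficients must be positive")
        if self.n_general < 3 or self.n_disease < 3:
            raise ValueError("population cohort sizes must be >= 3")
        if not (0 < self.cv_min < self.cv_max):
            raise ValueError("require 0 < cv_min < cv_max")
        if self.kappa < 0 or self.donor_base_var < 0:
            raise ValueError("donor variance components must be >= 0")
        total = sum(self.venn_quotas.values())
        if total > self.n_genes:
            raise ValueError(f"venn quotas ({total}) exceed n_genes ({self.n_genes})")

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    def replace(self, **kwargs) -> "SimSpec":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted truth accompanying a simulated artifact.

    ``genes`` is a per-gene frame (baseline means, per-condition log2 fold
    changes and DE flags, signature class, planted population CVs, planted
    stratum, exosome weights); ``reads`` holds per-read true origins for the
    exosome simulation.
    """

    genes: pd.DataFrame
    reads: pd.DataFrame | None = None


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draw with variance mu + phi*mu^2; Poisson limit for tiny phi."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = phi < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        size = 1.0 / phi[~tiny]
        p = size / (size + mu[~tiny])
        out[~tiny] = rng.negative_binomial(size, p)
    return out


def _gene_universe(spec: SimSpec) -> pd.DataFrame:
    """Shared per-seed gene universe: annotation, baselines and all plants."""
    rng = spec.rng("universe")
    n = spec.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    biotype = np.full(n, "protein_coding", dtype=object)
    n_lnc = round(spec.frac_lnc * n)
    lnc_idx = rng.choice(n, size=n_lnc, replace=False)
    biotype[lnc_idx] = "lncRNA"

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, n)
    silent = rng.random(n) < spec.frac_silent
    baseline[silent] = rng.lognormal(spec.silent_log_mean, spec.silent_log_sd,
                                     silent.sum())

    # condition-response plants drawn among expressed genes only
    venn = np.full(n, "none", dtype=object)
    order = rng.permutation(np.flatnonzero(~silent))
    pos = 0
    for cls in _VENN_CLASSES:
        q = int(spec.venn_quotas.get(cls, 0))
        venn[order[pos:pos + q]] = cls
        pos += q

    sign = np.where(rng.random(n) < spec.up_fraction, 1.0, -1.0)
    lfc = {c: np.zeros(n) for c in ("DHA", "EPA", "OA")}
    for cond in ("DHA", "EPA", "OA"):
        active = np.array([cond in v.split("_") if v != "none" else False for v in venn])
        mag = np.maximum(spec.lfc_min, np.abs(rng.normal(spec.lfc_mean, spec.lfc_sd, n)))
        lfc[cond][active] = sign[active] * mag[active]

    sig_class = np.array([_SIGNATURE_OF_VENN[v] for v in venn], dtype=object)

    # population CV: log-uniform background; signature genes planted into
    # known strata (extremes per quota, remainder mid-band so the planted
    # most:least ratios are exactly recoverable)
    cv = np.exp(rng.uniform(math.log(spec.cv_min), math.log(spec.cv_max), n))
    plant = np.full(n, "none", dtype=object)
    for cls, (n_most, n_least) in spec.strata_plants.items():
        members = np.flatnonzero(sig_class == cls)
        members = members[rng.permutation(len(members))]
        # quotas are "up to class size": a null or sparse plant just fills less
        n_most = min(n_most, len(members))
        n_least = min(n_least, len(members) - n_most)
        plant[members[:n_most]] = "most"
        plant[members[n_most:n_most + n_least]] = "least"
        plant[members[n_most + n_least:]] = "middle"
    # every other condition-responsive gene sits mid-band too, so DE-call
    # spillover between classes cannot contaminate the extreme strata
    plant[(venn != "none") & (plant == "none")] = "middle"
    most = plant == "most"
    least = plant == "least"
    middle = plant == "middle"
    cv[most] = rng.uniform(*spec.cv_plant_most, most.sum())
    cv[least] = rng.uniform(*spec.cv_plant_least, least.sum())
    cv[middle] = rng.uniform(*spec.cv_plant_mid, middle.sum())
    # planted-stratum genes get comfortable depth so the sampling (Poisson)
    # floor cannot push a low-CV plant out of its stratum
    baseline[least] = rng.lognormal(5.8, 0.3, least.sum())
    baseline[most] = np.maximum(baseline[most], 50.0)

    cv_disease = np.clip(cv * np.exp(rng.normal(0.0, spec.disease_cv_jitter, n)),
                         spec.cv_min * 0.9, spec.cv_max * 1.1)

    # co-expression modules: lncRNA hubs from the most-variable signature
    # plants, plus background coding members with boosted CV and depth
    module = np.full(n, -1, dtype=np.int64)
    loading = np.zeros(n)
    lnc_pool = list(np.flatnonzero(
        most & (biotype == "lncRNA")
        & np.isin(sig_class, ("DHA_only", "EPA_only", "DHA_and_EPA"))))
    coding_pool = list(np.flatnonzero(
        (venn == "none") & ~silent & (plant == "none")
        & (biotype == "protein_coding")))
    rng.shuffle(lnc_pool)
    rng.shuffle(coding_pool)
    n_modules = min(spec.n_modules, len(lnc_pool) // max(spec.module_n_lnc, 1),
                    len(coding_pool) // max(spec.module_n_coding, 1))
    for m in range(n_modules):
        hubs = [lnc_pool.pop() for _ in range(spec.module_n_lnc)]
        members = [coding_pool.pop() for _ in range(spec.module_n_coding)]
        module[hubs] = m
        loading[hubs] = 1.0
        module[members] = m
        negative = rng.random(len(members)) < spec.module_neg_frac
        loading[members] = np.where(negative, -1.0, 1.0)
        cv[members] = rng.uniform(0.4, 0.9, len(members))
        cv_disease[members] = np.clip(
            cv[members] * np.exp(rng.normal(0.0, spec.disease_cv_jitter,
                                            len(members))),
            spec.cv_min * 0.9, spec.cv_max * 1.1)
        baseline[members] = np.maximum(baseline[members], 100.0)

    shift = np.zeros(n)
    shifted = rng.random(n) < spec.disease_shift_frac
    shift[shifted] = rng.normal(0.0, spec.disease_shift_sd, shifted.sum())

    phi = spec.disp_a0 + spec.disp_a1 / baseline

    return pd.DataFrame(
        {
            "biotype": biotype,
            "baseline_mean": baseline,
            "phi": phi,
            "silent": silent,
            "venn_class": venn,
            "lfc_DHA": lfc["DHA"],
            "lfc_EPA": lfc["EPA"],
            "lfc_OA": lfc["OA"],
            "de_DHA": lfc["DHA"] != 0,
            "de_EPA": lfc["EPA"] != 0,
            "de_OA": lfc["OA"] != 0,
            "signature_class": sig_class,
            "pop_cv_general": cv,
            "pop_cv_disease": cv_disease,
            "plant_stratum": plant,
            "module": module,
            "loading": loading,
            "disease_shift_lfc": shift,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def simulate_hepatocyte_experiment(
    spec: SimSpec,
) -> tuple[CountMatrix, DesignTable, GeneTable, GroundTruth]:
    """Vehicle/DHA/EPA/OA treated-hepatocyte counts with planted fold changes.

    Counts are NB(mean = baseline * 2^lfc(condition) * depth, dispersion phi);
    the vehicle arm has lfc = 0 everywhere. The planted Venn quotas guarantee
    every DHA/EPA/OA intersection class is non-empty.
    """
    if spec.n_reps < 2:
        raise ValueError("n_reps must be >= 2 for any DE contrast")
    uni = _gene_universe(spec)
    rng = spec.rng("hepatocyte")

    conditions = ["vehicle", "DHA", "EPA", "OA"]
    sample_ids, cond_col, rep_col = [], [], []
    for cond in conditions:
        for r in range(1, spec.n_reps + 1):
            sample_ids.append(f"{cond}_r{r}")
            cond_col.append(cond)
            rep_col.append(r)
    libs = rng.lognormal(spec.lib_log_mean, spec.lib_log_sd, len(sample_ids))

    base = uni["baseline_mean"].to_numpy()
    phi = uni["phi"].to_numpy()
    counts = np.empty((len(uni), len(sample_ids)), dtype=np.int64)
    for j, cond in enumerate(cond_col):
        lfc = np.zeros(len(uni)) if cond == "vehicle" else uni[f"lfc_{cond}"].to_numpy()
        mu = base * 2.0 ** lfc * (libs[j] / 1e6)
        counts[:, j] = _nb_sample(rng, mu, phi)

    cm = CountMatrix(
        pd.DataFrame(counts, index=uni.index, columns=sample_ids),
        pd.Series(np.round(libs).astype(np.int64), index=pd.Index(sample_ids)),
    )
    design = DesignTable(pd.DataFrame({
        "sample_id": sample_ids,
        "condition": cond_col,
        "donor_id": "D1",
        "replicate": rep_col,
    }))
    genes = GeneTable.from_records(uni.index.tolist(), uni["biotype"].tolist(), "human")
    return cm, design, genes, GroundTruth(genes=uni)


def simulate_population_cohort(
    spec: SimSpec, cohort: str
) -> tuple[CountMatrix, GroundTruth]:
    """Population expression matrix with planted per-gene CV structure.

    Each individual's expected expression is drawn log-normally around the
    gene's baseline with sigma chosen so the biological CV equals the planted
    value (for a log-normal, CV^2 = exp(sigma^2) - 1); observed counts add
    Poisson sampling noise at the individual's sequencing depth. The disease
    cohort additionally shifts a planted subset of gene means.
    """
    if cohort not in ("general", "disease"):
        raise ValueError(f"cohort must be 'general' or 'disease', got {cohort!r}")
    uni = _gene_universe(spec)
    n_ind = spec.n_general if cohort == "general" else spec.n_disease
    if n_ind < 3:
        raise ValueError("cohort size must be >= 3")
    rng = spec.rng(cohort)

    cv = uni[f"pop_cv_{cohort}"].to_numpy()
    mean = uni["baseline_mean"].to_numpy().copy()
    if cohort == "disease":
        mean = mean * 2.0 ** uni["disease_shift_lfc"].to_numpy()
    sigma = np.sqrt(np.log1p(cv ** 2))

    libs = rng.lognormal(spec.lib_log_mean, spec.lib_log_sd + 0.05, n_ind)
    z = rng.standard_normal((len(uni), n_ind))
    # planted co-expression: module members share a latent factor; the
    # sqrt(rho) mixture keeps each gene's marginal variance (hence CV) intact
    module = uni["module"].to_numpy()
    if (module >= 0).any():
        n_mod = int(module.max()) + 1
        factors = rng.standard_normal((n_mod, n_ind))
        in_mod = module >= 0
        loading = uni["loading"].to_numpy()[in_mod, None]
        rho = spec.module_rho
        z[in_mod] = (math.sqrt(rho) * loading * factors[module[in_mod]]
                     + math.sqrt(1.0 - rho) * z[in_mod])
    lam = mean[:, None] * np.exp(z * sigma[:, None] - sigma[:, None] ** 2 / 2.0)
    counts = rng.poisson(lam * (libs / 1e6)[None, :])

    sample_ids = [f"{cohort[:3]}_{i:03d}" for i in range(n_ind)]
    cm = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=uni.index, columns=sample_ids),
        pd.Series(np.round(libs).astype(np.int64), index=pd.Index(sample_ids)),
    )
    return cm, GroundTruth(genes=uni)


def simulate_donor_panel(
    spec: SimSpec,
    truth: GroundTruth,
    gene_ids: Sequence[str],
    treatment: str = "DHA",
) -> pd.DataFrame:
    """Treatment/vehicle expression ratios across a panel of donors.

    Each ratio is ``2^lfc * exp(eps)`` with donor-level
    ``eps ~ N(0, donor_base_var + kappa * pop_cv^2)``; kappa > 0 makes the
    planted population CV predictive of the across-donor response CV.
    Returns a genes x donors frame of strictly positive ratios.
    """
    if treatment not in ("DHA", "EPA"):
        raise ValueError(f"treatment must be 'DHA' or 'EPA', got {treatment!r}")
    unknown = [g for g in gene_ids if g not in truth.genes.index]
    if unknown:
        raise ValueError(f"gene id(s) not in ground truth: {unknown[:5]}")
    rng = spec.rng("donors")
    sub = truth.genes.loc[list(gene_ids)]
    lfc = sub[f"lfc_{treatment}"].to_numpy()
    cv = sub["pop_cv_general"].to_numpy()
    tau = np.sqrt(spec.donor_base_var + spec.kappa * cv ** 2)
    eps = rng.standard_normal((len(sub), spec.n_donors)) * tau[:, None]
    ratios = 2.0 ** lfc[:, None] * np.exp(eps)
    donors = [f"donor{d + 1:02d}" for d in range(spec.n_donors)]
    return pd.DataFrame(ratios, index=pd.Index(gene_ids, name="gene_id"), columns=donors)


def with_mouse_genes(gene_table: GeneTable, n_mouse: int) -> GeneTable:
    """Extend a human gene table with simulated mouse genes (ids ``M*``)."""
    mouse_ids = [f"M{i:05d}" for i in range(n_mouse)]
    extra = GeneTable.from_records(mouse_ids, "protein_coding", "mouse")
    return GeneTable(pd.concat([gene_table.table, extra.table]))


def simulate_exosome_reads(
    spec: SimSpec,
    gene_table: GeneTable,
    boost_genes: Sequence[str] = (),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Exosomal alignment records against a combined prefixed reference.

    Emits per-read alignments with contigs ``human_<gene>`` / ``mouse_<gene>``.
    Human reads carry a top-score human alignment (a fraction also carry a
    lower-score mouse alignment); mouse reads align to mouse contigs only;
    ambiguous reads carry equal-score alignments to both genomes. Per-gene
    human abundance weights place a known subset — including any
    ``boost_genes`` — in the top ``exo_top_frac`` by read count.
    """
    human = gene_table.genes_of_species("human")
    mouse = gene_table.genes_of_species("mouse")
    if not human or not mouse:
        raise ValueError("gene_table must contain both human and mouse genes")
    boost = list(dict.fromkeys(boost_genes))
    unknown = set(boost) - set(human)
    if unknown:
        raise ValueError(f"boost gene(s) not human genes: {sorted(unknown)[:5]}")

    rng = spec.rng("exosome")
    n_top = math.ceil(spec.exo_top_frac * len(human))
    if len(boost) > n_top:
        raise ValueError(f"more boost genes ({len(boost)}) than top slots ({n_top})")
    others = [g for g in human if g not in set(boost)]
    filler = rng.choice(len(others), size=n_top - len(boost), replace=False)
    top_set = boost + [others[i] for i in sorted(filler)]
    is_top = pd.Series(False, index=pd.Index(human, name="gene_id"))
    is_top[top_set] = True

    weights = rng.uniform(0.05, 1.0, len(human))
    weights[is_top.to_numpy()] = rng.uniform(5.0, 10.0, n_top)
    pweights = weights / weights.sum()

    rows: list[tuple[str, str, str, float]] = []
    origins: list[tuple[str, str]] = []

    human_arr = np.asarray(human, dtype=object)
    assign = rng.choice(len(human), size=spec.n_human_reads, p=pweights)
    secondary = rng.random(spec.n_human_reads) < spec.mouse_secondary_frac
    mouse_pick = rng.choice(len(mouse), size=spec.n_human_reads)
    for i in range(spec.n_human_reads):
        rid = f"hr{i:07d}"
        g = human_arr[assign[i]]
        rows.append((rid, f"human_{g}", g, 60.0))
        if secondary[i]:
            mg = mouse[mouse_pick[i]]
            rows.append((rid, f"mouse_{mg}", mg, 30.0))
        origins.append((rid, "human"))

    mouse_assign = rng.choice(len(mouse), size=spec.n_mouse_reads)
    for i in range(spec.n_mouse_reads):
        rid = f"mr{i:07d}"
        mg = mouse[mouse_assign[i]]
        rows.append((rid, f"mouse_{mg}", mg, 60.0))
        origins.append((rid, "mouse"))

    amb_h = rng.choice(len(human), size=spec.n_ambiguous, p=pweights)
    amb_m = rng.choice(len(mouse), size=spec.n_ambiguous)
    for i in range(spec.n_ambiguous):
        rid = f"ar{i:07d}"
        g, mg = human_arr[amb_h[i]], mouse[amb_m[i]]
        rows.append((rid, f"human_{g}", g, 60.0))
        rows.append((rid, f"mouse_{mg}", mg, 60.0))
        origins.append((rid, "ambiguous"))

    records = pd.DataFrame(rows, columns=["read_id", "contig", "gene_id", "score"])
    truth_genes = pd.DataFrame(
        {"exo_weight": weights, "exo_top": is_top.to_numpy()},
        index=pd.Index(human, name="gene_id"),
    )
    truth_reads = pd.DataFrame(origins, columns=["read_id", "true_origin"])
    return records, GroundTruth(genes=truth_genes, reads=truth_reads)


def simulate_gene_sets(
    spec: SimSpec,
    gene_ids: Sequence[str],
    n_sets: int = 20,
    size_range: tuple[int, int] = (20, 80),
    modules: Mapping[int, Sequence[str]] | None = None,
) -> GeneSetCollection:
    """Gene sets over a given universe, for enrichment exercises.

    ``modules`` (module id -> coding member gene ids) adds one pathway per
    co-expression module containing its members plus random padding, so a
    module's hub lncRNAs genuinely enrich for that pathway; the remaining
    sets are random draws.
    """
    rng = spec.rng("genesets")
    gene_ids = list(gene_ids)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    if modules:
        pool = [g for g in gene_ids]
        for m in sorted(modules):
            members = [g for g in modules[m] if g in set(gene_ids)]
            pad = rng.choice(len(pool), size=min(20, len(pool)), replace=False)
            full = sorted(set(members) | {pool[i] for i in pad})
            name = f"PATH_M{m:02d}"
            sets[name] = full
            descriptions[name] = f"pathway of co-expression module {m}"
    for k in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(gene_ids))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        name = f"SET{k:03d}"
        sets[name] = [gene_ids[i] for i in sorted(members)]
        descriptions[name] = f"synthetic gene set {k}"
    return GeneSetCollection(sets=sets, descriptions=descriptions, universe=gene_ids)
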