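"""Exosomal read-origin partitioning and the top-20% detectability filter.

Reads from a liver-humanized mouse map to a combined reference with
human_/mouse_ contig prefixes; only human-specific reads are kept, genes
are ranked by read count, and the top 20% intersect the most-variable
signature genes to give accessible biomarker candidates.
"""
import omega3sig as o

spec = o.SimSpec(rng_seed=1)
cfg = o.RunConfig(rng_seed=1)
_, _, genes, truth = o.simulate_hepatocyte_experiment(spec)
combined = o.with_mouse_genes(genes, spec.n_mouse_genes)
boost = truth.genes.index[truth.genes["plant_stratum"] == "most"].tolist()
records, exo_truth = o.simulate_exosome_reads(spec, combined, boost_genes=boost)

origins = o.assign_origin(records)
print("origin tally:", origins["origin"].value_counts().to_dict())
counts = o.quantify_human_genes(origins, combined)
full = counts.reindex(combined.genes_of_species("human"), fill_value=0.0)
detectable = o.top_fraction(full, cfg.exo_top_frac)
print(f"detectable genes (top {cfg.exo_top_frac:.0%} by count): {len(detectable)}")

classes = {cls: truth.genes.index[(truth.genes["signature_class"] == cls)
                                  & (truth.genes["plant_stratum"] == "most")]
           .tolist()
           for cls in ("DHA_only", "EPA_only", "DHA_and_EPA")}
print(o.biomarker_intersection(detectable, classes).to_string(index=False))
# ambiguous (equal best score on both genomes) reads are dropped: only
# human-specific reads say anything about the humanized liver
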