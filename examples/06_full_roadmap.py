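"""Run the whole biomarker-selection roadmap end to end.

simulate -> filter -> DE (3 contrasts) -> signatures -> population CV ->
stratified intersection -> donor validation -> lncRNA network -> exosome
filter -> biomarker report. Deterministic for a fixed seed; all stage TSVs
land in the output directory.
"""
import omega3sig as o

cfg = o.RunConfig(rng_seed=1)
report = o.run_roadmap(cfg, out_dir="roadmap_out")
print("\n".join(report.summary_lines()))
# the final biomarker lists are the exosome-detectable, most-variable,
# omega-3-specific genes per signature class
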