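"""Run the complete pipeline on a small demo cohort.

simulate -> build -> metrics -> compare -> nbs -> roc, writing a fully
reproducible output tree (identical config + seed => identical bytes).
"""

from strucnet import RunConfig, run_pipeline, tree_hash

config = RunConfig.demo(output_dir="scratch/pipeline_demo", seed=42)
bundle = run_pipeline(config)

table = bundle["metric_table"]
print("metric table:", table.shape[0], "subjects x", table.shape[1], "columns")
print(table[["lp", "eg", "eloc", "sigma"]].groupby(
    bundle["manifest"].set_index("subject_id")["group"]).mean().round(3))

for (contrast, tail), res in bundle["nbs"].items():
    sig = res.significant()
    print(f"NBS {contrast[0]} vs {contrast[1]} ({tail}): "
          f"{len(sig)} significant component(s)"
          + (f", largest {sig[0].size} edges, p={sig[0].p_value:.3f}" if sig else ""))

print("output tree hash:", tree_hash(config.output_dir)[:16], "...")
# Re-running with the same seed reproduces this hash exactly; the comparison
# tables under compare/ and nbs/ are the study-style outputs.
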