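"""The configuration-driven end-to-end pipeline.

One config mapping drives simulate -> score -> dual-classify -> prevalence ->
Burstein -> statistics; the same run is available from the shell as
``dualsubtype run --config cfg.yaml --out-dir out/``.
"""

import json

import dualsubtype as ds

report = ds.run_pipeline(
    {
        "n_samples": 800,
        "dual_fraction": 0.05,
        "bootstrap_b": 400,
        "seed": 20,
        "prevalence_n_iter": 500,
    },
    out_dir="scratch/pipeline_demo",
)

print("accounting:", report["accounting"]["kind_counts"])
print("truth vs call:", {k: round(v, 4) if v is not None else None
                         for k, v in report["truth_vs_call"].items()})
print("prevalence: %.2f%% (CI %.2f-%.2f)" % (
    report["prevalence"]["estimate_pct"], *report["prevalence"]["ci_pct"]))
print("pCR HER2-single vs Luminal-HER2: %.1f%% vs %.1f%%" % (
    report["stats"]["pcr_her2_single_pct"], report["stats"]["pcr_luminal_her2_pct"]))
print("\nreport files in scratch/pipeline_demo/:",
      "dual_calls.csv, thresholds.json, summary.json")
print(json.dumps(report["accounting"]["kind_by_standard"], indent=1))
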