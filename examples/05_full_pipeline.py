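"""One-config full pipeline run with ledger and manifest.

The pipeline chains phenotyping, both workflows and classification from a
single declarative config (here using the in-memory simulator; point
``variant_table``/``pedigree_file``/``phenotype_file`` at your own files
instead).  The manifest's content hash makes reruns verifiable.
"""

import json

from famprio.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig.from_dict({
    "simulate": {
        "n_families": 4,
        "n_background": 500,
        "planted": [{"f1": 1.0, "f0": 0.0, "families": [0, 1]}],
        "missingness": 0.0,
        "low_nviq_rate": 0.0,
    },
    "seed": 7,
    "outdir": "scratch/demo_run",
})
result = run_pipeline(config)

print("stage ledger:")
print(json.dumps(result.ledger, indent=2, sort_keys=True))
print("\nverdicts for prioritized variants:")
for key, verdict in result.verdicts.items():
    p = result.fisher_p.get(key)
    print(f"  {key}: {verdict.verdict}  (burden p = {p:.3g})" if p is not None
          else f"  {key}: {verdict.verdict}")
print("\nmanifest content hash:", result.manifest["content_hash"][:16], "...")
print("outputs in scratch/demo_run: report.tsv, trace.tsv, ledger.json, manifest.json")
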