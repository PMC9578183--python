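"""One-call pipeline run from a config, writing a full run directory.

Equivalent to `weakrel demo` on the command line; the manifest records the
config hash, seeds and every stage output path.
"""

import json

from weakrel import RunConfig, run_pipeline

config = RunConfig(
    seed=5,
    output_dir="scratch/demo_run",
    corpus={"n_abstracts": 300, "edge_types": ["CbG", "DaG"]},
    target_edge="CbG",
    sources=["CbG", "DaG"],
    sizes=[2, 10, 20],
    n_repeats=3,
    discriminative=True,
)
manifest = run_pipeline(config)
print(json.dumps(manifest["stages"], indent=2, default=str))
# The run directory now holds the candidate TSV, label matrix, fitted
# parameters, experiment records/summary, and the promotion report.
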