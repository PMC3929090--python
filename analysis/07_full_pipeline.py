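"""Run every stage through the single-config orchestrator and show the
run log's filter-step accounting."""

import json

from common import DEMO_SPEC, RESULTS

from cnvpipe import PipelineConfig, run_pipeline

out = run_pipeline(
    PipelineConfig(
        out_dir=RESULTS / "pipeline",
        spec=DEMO_SPEC,
        n_perm=2000,
        seed=DEMO_SPEC.seed,
        validate_lrr=True,
    )
)
log = json.loads((out / "run_log.json").read_text())
print(f"pipeline finished; outputs in {out}")
for key in sorted(log):
    print(f"  {key}: {log[key]}")
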