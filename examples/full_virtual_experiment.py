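"""End-to-end virtual experiment with on-disk artifacts.

Runs the complete pipeline -- randomized session, intermittent-control
simulation, set-point reconstruction, stage-2 battery, stage-3 report --
for three virtual participants on the zero-order system and prints the
four refractory-duration metrics.
"""

import tempfile
from pathlib import Path

from ictrack import ICParams, RunConfig, SystemSpec, run_experiment

out = Path(tempfile.mkdtemp()) / "experiment"
config = RunConfig(
    system=SystemSpec(order=0),
    params=ICParams(open_loop_interval=0.35, feedback_delay=0.14,
                    trigger_mode="external"),
    seed=2024,
    controller="intermittent",
    participants=3,
    repetitions=1,
    out_dir=out,
    save_trials=False,
)
result = run_experiment(config)

print(f"{len(result.table)} step pairs reconstructed; artifacts in {out}")
print(result.report.to_markdown())
print()
print("The ANOVA metric and the slope -1 intercept both recover the")
print("configured 0.35 s open-loop interval (the metric is quantized to the")
print("ISI grid); mean RT1 recovers the 0.14 s feedback delay.")
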