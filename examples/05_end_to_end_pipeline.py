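"""Run the full simulate -> calibrate -> solve -> report pipeline.

Two conditions are simulated under the two-state occupancy model (a strong
client at f_occupy = 1/16 and a weak one at 1/4.5, 33 droplets each with 5%
measurement noise), the reporter calibration is built from its own simulated
table, and the per-condition report shows how well the solver recovers the
programmed enhancement factors.
"""

import tempfile
from pathlib import Path

from condensate_proximity import RunConfig, run_end_to_end

out = Path(tempfile.mkdtemp()) / "demo_run"
config = RunConfig(output_dir=str(out), seed=0)  # default two-condition demo
report = run_end_to_end(config)

print(report.to_string(index=False))
print(f"\nintermediates in {out}:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
# mean_enhancement ~16 and ~4.5 recover the simulated truths; the matching
# |epsilon| columns (~1.65 and ~0.90 kcal/mol) are the implied per-molecule
# client-scaffold binding free energies at 300 K.
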