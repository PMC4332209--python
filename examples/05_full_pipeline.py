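"""End-to-end run: simulate two groups, quantify, fit, compare.

Simulates four control channels and four delayed-nucleation channels
(nucleation shifted +57 s, the published effect size), writes TIFF
stacks with ground truth, quantifies them into TFI/TAC traces, fits the
quadratic model per channel and reports the group comparison.

Equivalent shell command:  thromboflux full --seed 7 --out runs/demo
"""

import json
from pathlib import Path

from thromboflux import RunConfig, run_full

out = Path("scratch/example_run")
config = RunConfig(mode="full", output_dir=str(out), seed=7)
report = run_full(config)

lag = report["comparison"]["TFI"]["lag_s"]
print(f"output files    : {len(report['manifest']['files'])} "
      f"(manifest with SHA-256 in {out}/manifest.json)")
print(f"WT lag (est.)   : {lag['wt_mean']:.1f} ± {lag['wt_se']:.1f} s (n={lag['wt_n']})")
print(f"KO lag (est.)   : {lag['ko_mean']:.1f} ± {lag['ko_se']:.1f} s (n={lag['ko_n']})")
print(f"difference      : {lag['difference']} s (simulated truth: 57.1 s shift)")
print(f"t = {lag['t']:.2f}, p = {lag['p']:.4f} -> "
      f"{'significant' if lag['significant'] else 'not significant'} at 0.05")
print("\nfull comparison table:", json.dumps(report["comparison"]["TFI"],
                                             indent=2)[:200], "...")
# The pipeline recovers the simulated lag shift from the rendered images
# alone — nucleation times are never passed to the analysis stages.
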