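"""Run a reduced noise-ladder sweep and compare LCMV with pLCMV.

The full protocol sweeps six benchmark source locations (two deep, four
shallow) over 12 noise levels with 50 shared noise realizations per level;
this example uses 5 reps to finish in about a minute.  Per-level mean
location errors and the paired bootstrap comparison are printed.
"""

import dataclasses

from plsbeam import ExperimentConfig, compare_methods
from plsbeam.harness import run_noise_sweep

cfg = dataclasses.replace(ExperimentConfig(), n_reps=5)
result = run_noise_sweep(cfg)
print(result.per_level_summary().to_string(index=False))

summary = compare_methods(result, n_boot=500)
print(f"\nlevels where pLCMV mean error <= LCMV: "
      f"{summary['levels_plcmv_le_lcmv']} of {summary['n_levels']}")
for t in summary["trend"]:
    print(f"{t['method']}: Kendall tau {t['tau']:+.3f}, "
          f"p(error increases with noise) = {t['p_increasing']:.3f}")
# A mean error of 0.0 at a level means every repetition localized the exact
# source grid point; with a matched forward model the desk-scale problem is
# easy at high SNR, and differences between methods appear only at the
# noisiest levels.
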