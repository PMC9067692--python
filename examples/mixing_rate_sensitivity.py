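"""Sensitivity of cooperation to the between-group mixing rate.

Sweeps the imitation mixing rate m at group size 60 in the compulsory
scenario (3 replicates per value, ~1 minute).  Between-group imitation
erodes the between-group variation that group selection feeds on: past a
threshold, cooperation collapses entirely.
"""

from pggsim import ParamSet, sensitivity_sweep

base = ParamSet(n=60, scenario="compulsory", replicates=3)
table = sensitivity_sweep("m", (0.002, 0.05, 0.15), base, root_seed=42)

for _, row in table.iterrows():
    print(
        f"m={row.m:.3f}: cooperation {row.freq_cooperation_mean:.3f} "
        f"(sd {row.freq_cooperation_sd:.3f})"
    )
# Cooperation persists at low mixing, degrades near m ~ 0.05 and is gone
# by m ~ 0.15: high payoffs then diffuse between groups faster than group
# selection can amplify them.
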