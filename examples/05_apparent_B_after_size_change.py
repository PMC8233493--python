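"""Apparent B during a population-size transient, analytically.

BGS rescales the local effective size by B, and regions with smaller Ne
respond faster to size changes. The apparent B-hat = pi_selected/pi_neutral
therefore dips below the equilibrium B during a decline transient and
rises above it during growth, before returning to B at the new
equilibrium.
"""

import numpy as np

from bgsinfer import apparent_B_after_change, exponential_growth, instantaneous_decline

B0 = 0.8
for dem in (instantaneous_decline(), exponential_growth()):
    print(f"\n{dem.label}: ancestral B = {B0}")
    for t in (0, 100, 250, 500, 1000, 5000, 50000):
        bhat = apparent_B_after_change(B0, dem, t).B
        print(f"  t = {t:>6} generations: apparent B = {bhat:.3f}")
# Decline: B-hat sinks toward ~0.67 mid-transient before recovering to
# 0.8; growth pushes B-hat toward 1. Measuring B during a transient thus
# mis-states the equilibrium strength of background selection.
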