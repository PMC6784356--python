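"""Spectral unmixing quality via the area-under-curve (AUC) metric.

Simulates a monochromator sweep (500-625 nm in 2 nm steps) of a mosaic
sensor with inter-channel cross-talk, then compares the AUC of each
normalized channel response before and after spectral unmixing.  Sharper
(smaller-AUC) responses after unmixing mean less spectral mixing between
the Fabry-Perot channels.
"""

import numpy as np

from oximap import make_sensitivity_fixture, monochromator_sweep, spectral_response_auc

sens = make_sensitivity_fixture(crosstalk=0.2)
mixed = [spectral_response_auc(c) for c in monochromator_sweep(sens)]
unmixed = [spectral_response_auc(c)
           for c in monochromator_sweep(sens, unmixed=True)]

centers = [c for c in sens.channel_centers_nm if 500 <= c <= 625]
print(f"{'center_nm':>9} {'AUC mixed':>10} {'AUC unmixed':>12} {'ratio':>6}")
for c, m, u in zip(centers, mixed, unmixed):
    print(f"{c:9.0f} {m:10.2f} {u:12.2f} {m / u:6.2f}")
print(f"\nmean AUC reduction factor: {np.mean(mixed) / np.mean(unmixed):.2f}")
print("AUC is in nm: the effective width of the unit-peak response curve."
      "\nUnmixing narrows every channel, improving spectral selectivity.")
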