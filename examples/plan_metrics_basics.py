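"""Plan-quality metrics on a hand-made dose distribution.

Shows the voxel-exact conventions: cumulative DVH, dose-at-volume by
descending rank, the power-mean gEUD, and the LKB NTCP.
"""

import numpy as np

import autofmo as af

dose = np.array([70.0, 74.0, 78.0, 82.0, 78.0, 78.0])
mask = np.ones(6, dtype=bool)

print("doses (Gy):", dose)
print(f"V(74 Gy)    = {af.volume_at_dose(dose, mask, 74.0):.1f}%   (voxels at/above 74 Gy)")
print(f"D_50%       = {af.dose_at_volume(dose, mask, 50.0):.1f} Gy (hottest half gets at least this)")
print(f"gEUD(a=1)   = {af.geud(dose, mask, 1.0):.2f} Gy (the mean dose)")
print(f"gEUD(a=8)   = {af.geud(dose, mask, 8.0):.2f} Gy (weighted toward hot voxels)")
p = af.ntcp_lkb(dose, mask, td50=76.9, m=0.13, n=0.09)
print(f"LKB NTCP    = {p:.3f}  (TD50=76.9 Gy, m=0.13, n=0.09; serial-type organ)")
print("\nNTCP is the probit of (gEUD_{1/n} - TD50)/(m TD50): a uniform dose at")
print("TD50 gives exactly 0.5; small n makes the organ max-dose driven.")
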