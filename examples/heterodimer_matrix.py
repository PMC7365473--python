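"""Contact-time matrix for a panel of rods (ordered straight/bent pairs).

Every ordered pair (straight rod, shifted-and-bent rod) gets its own
contact-time profile; the diagonal holds homo-dimers.  Here the panel is
two synthetic rods differing in tip charge — a toy analogue of comparing
myosin isoforms with stronger and weaker assembly domains.
"""

import numpy as np

import minifil as mf

strong = mf.make_periodic_rod(mf.SyntheticRodSpec(seed=0), label="strong_tip")
weak = mf.make_periodic_rod(
    mf.SyntheticRodSpec(seed=0, tip_amplitude=8.0), label="weak_tip"
)
sp = strong.spacing
s_grid = np.arange(0, 700, 14) * sp  # first three repeat staggers, coarse

mat = mf.heterodimer_matrix(
    [strong, weak], "parallel", s_grid=s_grid,
    e_params=mf.ElectrostaticParams(), wlc_params=mf.WLCParams(),
)
print(mat.summary().to_string(index=False))
print()
homo_strong = mat.profile("strong_tip", "strong_tip").peak_time
homo_weak = mat.profile("weak_tip", "weak_tip").peak_time
print(f"homo-dimer peak contact times: strong {homo_strong:.3g}, "
      f"weak {homo_weak:.3g} nm^2")
print("A weaker (less charged) tip shortens contact times across the row —")
print("the matrix ranks which pairings persist longest at which stagger.")
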