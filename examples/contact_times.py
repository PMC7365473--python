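"""Mean contact times of zipping rod pairs versus stagger.

After the tip attaches at stagger s with a 3.6 nm initial contact, the
overlap diffuses in V(L_o) between a reflecting boundary at L_max and an
absorbing boundary at zero overlap.  The mean first passage time D*T1 (nm^2)
measures how long a stagger survives; long-lived staggers are the ones
observed in minifilaments.
"""

import numpy as np

import minifil as mf

rod = mf.make_periodic_rod()
e_params, wlc = mf.ElectrostaticParams(), mf.WLCParams()

profiles = {}
for orientation in ("parallel", "antiparallel"):
    prof = mf.contact_time_profile(
        rod, rod, orientation, e_params=e_params, wlc_params=wlc
    )
    profiles[orientation] = prof
    peaks = np.round(prof.peaks() / rod.spacing).astype(int)
    print(f"{orientation}: global peak D*T1 = {prof.peak_time:.3g} nm^2 "
          f"at s = {prof.peak_stagger:.1f} nm")
    print(f"  peak staggers (sites): {peaks}")

ratio = profiles["antiparallel"].peak_time / profiles["parallel"].peak_time
print()
print(f"antiparallel / parallel peak contact time: {ratio:.0f}x")
print("Antiparallel dimers far outlive parallel ones — they nucleate the")
print("minifilament; parallel rods attach transiently at the repeat staggers.")
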