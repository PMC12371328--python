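"""Build MCAR and diversity-informed MNAR evaluation masks.

Run:  python examples/03_masking_mechanisms.py
"""

import numpy as np

from phylodiff.fixtures import golden_small
from phylodiff.missingness import mcar_mask, mnar_mask
from phylodiff.preprocess import shannon_index

profile, _, _ = golden_small()

mcar = mcar_mask(profile.observed, r=0.4, seed=0)
print("MCAR r=0.4: hidden", int(mcar.target.sum()), "of",
      int(profile.observed.sum()), "timepoints",
      f"(empirical rate {mcar.target.mean():.2f})")
# every subject keeps at least one conditional timepoint
print("min conditional timepoints per subject:", mcar.cond.sum(1).min())

mnar = mnar_mask(profile, r=0.4)
s = 0
H = [shannon_index(profile.values[s, l]) for l in range(5)]
print(f"\nMNAR r=0.4, subject 0: Shannon H = {np.round(H, 3)}")
print("hidden timepoints:", np.flatnonzero(mnar.target[s]),
      "<- the highest-diversity samples are the ones that go missing")
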