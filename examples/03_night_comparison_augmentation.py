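"""The pairwise night-comparison augmentation.

A subject with a migraine nights and b non-migraine nights yields only
a + b single-night observations — too few for cross-validation.  Using
signed differences between nights instead expands this to
a·b + b(b−1)/2 observations.  The script reproduces the bookkeeping for
the two extreme study-cohort shapes and shows one observation's
provenance.
"""

import numpy as np

from migrasleep import (NightFeatureVector, build_comparison_matrix,
                        count_observations)
from migrasleep.features import N_FEATURES

rng = np.random.default_rng(0)
for n_mig, n_non in [(17, 12), (14, 21)]:
    nights = [NightFeatureVector(f"m{i}", "S1", "pre_migraine",
                                 rng.normal(size=N_FEATURES))
              for i in range(n_mig)]
    nights += [NightFeatureVector(f"n{i}", "S1", "non_migraine",
                                  rng.normal(size=N_FEATURES))
               for i in range(n_non)]
    obs = build_comparison_matrix(nights, seed=0)
    print(f"{n_mig} migraine + {n_non} non-migraine nights "
          f"-> {len(obs)} comparison observations "
          f"(closed form: {count_observations(n_mig, n_non)})")

o = obs[0]
print(f"\nfirst observation: {o.label}, left={o.left_night_id}, "
      f"right={o.right_night_id}, sign={o.sign:+d}")
# Migraine comparisons are always migraine-minus-non-migraine (sign +1);
# non-migraine pairs are computed once with a random sign, so the matrix
# is stochastic and evaluation regenerates it per repetition.
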