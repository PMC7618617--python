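"""Sleep Regularity Index on constructed series, the Monte-Carlo null,
and outlier winsorization.

The SRI compares sleep/wake state at minutes 24 h apart: 100 means every
day repeats exactly, 0 is what random sleep produces, -100 means each day
is the previous one inverted.
"""

import numpy as np

from sleepreg import compute_sri, simulate_null, winsorize_sri

rng = np.random.default_rng(0)

# a 1,440-minute day template: asleep 23:00-07:00
day = np.zeros(1440)
day[1380:] = 1
day[:420] = 1

print("identical days     :", compute_sri(np.tile(day, 7)).sri_raw)
print("inverted second day:", compute_sri(np.concatenate([day, 1 - day])).sri_raw)
random_sleep = (rng.random(2 * 1440) < 0.5).astype(float)
print("random sleep       : %.2f" % compute_sri(random_sleep).sri_raw)

# The null distribution under random sleep defines the winsorization
# cutoff: values below it are indistinguishable from noise and replaced.
null = simulate_null(n_sims=100_000, seed=1)
print("null mean %.3f sd %.3f  99%% range (%.2f, %.2f)"
      % (null.mean, null.sd, null.q005, null.q995))

observed = np.array([-25.0, -3.0, 41.0, 78.0])
final, replaced = winsorize_sri(observed, null, seed=2)
print("observed :", observed)
print("winsorized:", np.round(final, 2), " replaced:", replaced)
# Only the -25 (below the ~-6.8 cutoff) is replaced by a null draw;
# everything else passes through untouched.
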