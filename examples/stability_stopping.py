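"""Stability of an extraction stream and the stopping rule.

When the full EFM set is unavailable, representativeness cannot be
measured — but a method can be compared with itself: the mean relative
error between the proportions p_k(r) after k EFMs and p_{k-d}(r) an
offset d earlier.  Once that self-comparison stays below a threshold for
several consecutive checkpoints, further extraction is unlikely to change
the estimated parameters.
"""

import numpy as np

from piefm import fixtures as fx
from piefm import metrics as mx
from piefm.oracle import enumerate_bruteforce

net = fx.make_random(n_met=5, n_rxn=12, density=0.4, rng_seed=20)
efms = [e.support for e in enumerate_bruteforce(net).efms]

# emulate a long extraction stream by sampling the full set with replacement
rng = np.random.default_rng(0)
stream = [efms[i] for i in rng.integers(len(efms), size=2000)]

d = 200
checkpoints = list(range(2 * d, len(stream) + 1, 200))
trace = mx.stability_trace(stream, d=d, checkpoints=checkpoints)
for k, v in zip(trace.checkpoints, trace.values):
    print(f"k={k:5d}  mre(p_k, p_k-{d}) = {v:.4f}")

stop = mx.stopping_index(trace, threshold=0.05, consecutive=3)
print(f"stopping point (3 consecutive checkpoints < 0.05): k={stop}")
# The error decays as the cumulative proportions converge; the stopping
# index marks where the stream stopped telling us anything new.
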