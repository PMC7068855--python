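"""p-value -> score threshold conversion for a hand-sized motif.

The score of a random window under the background model has a discrete
distribution that a per-position dynamic program computes exactly (on a
discretized score grid).  The threshold for p is the smallest score whose
upper tail mass is <= p: smaller p-values give higher thresholds.
"""

import numpy as np

from pwmgemm import PWM, score_distribution

# one-column toy motif: weights (A, C, G, T) = (1, -1, -1, 0) bits
pwm = PWM("toy", np.array([[1.0], [-1.0], [-1.0], [0.0]]))
dist = score_distribution(pwm, epsilon=1.0)

print("score PMF under a uniform background:", dist.as_dict())
for p in (1.0, 0.5, 0.25, 0.1):
    print(f"  p = {p:<5} -> threshold {dist.threshold(p):+.1f} bits "
          f"(realized p-value {dist.pvalue(dist.threshold(p)):.4f})")
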