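"""PWM threshold calibration: from a p-value to a log-odds cutoff.

Converts a frequency matrix to a natural-log log-odds PWM under a 40% GC
background and calibrates score thresholds for several p-values using the
exact background score distribution (column-wise convolution, no word
enumeration).
"""

import numpy as np

import sitefree as sf
from sitefree.synthetic import toy_pwm

bg = sf.make_background(0.4)
freq = toy_pwm(8, 0.9, np.random.default_rng(0), motif_id="demo")
pwm = sf.frequency_to_pwm(freq, bg, pseudocount_scale=1.0)
dist = sf.score_distribution(pwm, bg, resolution=1000)

print(f"motif length     : {pwm.length}")
print(f"score range      : [{pwm.min_score:.3f}, {pwm.max_score:.3f}]")
for p in (0.05, 0.01, 0.003, 0.001):
    t = sf.threshold_for_pvalue(dist, p)
    print(f"p = {p:<6g} -> threshold {t:.3f}")

# Each threshold t is the smallest score whose probability of being reached
# by a random background 8-mer is at most p; a stricter p raises t, so fewer
# windows are called sites during scanning and removal.
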