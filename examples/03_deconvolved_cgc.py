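"""Why deconvolve: HRF latency can reverse causal direction on raw BOLD.

Two regions with true coupling SRC -> TGT, but the source's hemodynamic
response peaks 2 s LATER than the target's.  On raw BOLD the target's
earlier response masquerades as the cause; estimating each region's HRF
from the task inputs and Wiener-deconvolving to pseudo-neural signals
restores the true temporal precedence.
"""
import numpy as np

from hemiflow import (
    build_paradigm,
    cgc_matrix,
    convolve_and_sample,
    deconvolve,
    estimate_hrf,
    simulate_neural_signals,
)
from hemiflow.cgc import preprocess_series
from hemiflow.hrf import CANONICAL
from hemiflow.synthetic import GroundTruthNetwork

paradigm = build_paradigm(8, 30, 3)  # 160 volumes
a = np.zeros((2, 2, 1))
a[0, 0, 0] = a[1, 1, 0] = 0.3
a[1, 0, 0] = 0.4  # SRC -> TGT at lag 1
hrfs = [CANONICAL.with_latency_offset(2.0), CANONICAL]  # source is slower
net = GroundTruthNetwork(["SRC_L", "TGT_R"], a, 1.0, hrfs)

raw_err = dec_err = 0
n = 50
for s in range(n):
    rng = np.random.default_rng(s)
    latent = simulate_neural_signals(net, paradigm, input_gain=2.0, rng=rng)
    bold = convolve_and_sample(latent, hrfs, 3.0, noise_sd=0.5, rng=rng)

    F_raw = cgc_matrix(preprocess_series(bold), order=1)
    raw_err += F_raw[1, 0] > F_raw[0, 1]

    rows = []
    for i in range(2):
        est = estimate_hrf(bold[i], paradigm)
        rows.append(deconvolve(bold[i], est).values)
    F_dec = cgc_matrix(preprocess_series(np.vstack(rows)), order=1)
    dec_err += F_dec[1, 0] > F_dec[0, 1]

print(f"direction-reversal rate on raw BOLD:     {raw_err / n:.2f}")
print(f"direction-reversal rate after deconvolution: {dec_err / n:.2f}")
# A reversal means the pipeline scored TGT->SRC above the true SRC->TGT;
# the drop after deconvolution is the method's core motivation.
est = estimate_hrf(bold[0], paradigm)
print(f"estimated source time-to-peak: {est.time_to_peak_s:.1f} s "
      f"(true {hrfs[0].time_to_peak_s:.1f} s)")
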